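"""Psychrometrics and the big-leaf Penman–Monteith model.

Conventions (all SI unless noted): temperature in degC, pressures in kPa,
fluxes in W m-2, conductances in m s-1.  The forward model is the standard
big-leaf formulation

    LE = (Delta*A + rho*cp*Ga*VPD) / (Delta + gamma*(1 + Ga/Gs))

with available energy A approximated by H + LE; the inversion solves the same
equation for the surface conductance Gs.
"""

from __future__ import annotations

import numpy as np

CP = 1004.834          # specific heat of air, J kg-1 K-1
RD = 287.0586          # gas constant of dry air, J kg-1 K-1
EPS = 0.622            # molecular weight ratio water vapor / dry air
P0 = 101.325           # standard sea-level pressure, kPa


def esat(ta):
    """Saturation vapor pressure (kPa) at air temperature ta (degC), Magnus form."""
    ta = np.asarray(ta, dtype=float)
    return 0.6108 * np.exp(17.27 * ta / (ta + 237.3))


def esat_slope(ta):
    """Slope of the saturation vapor-pressure curve, kPa K-1."""
    ta = np.asarray(ta, dtype=float)
    return 4098.0 * esat(ta) / (ta + 237.3) ** 2


def latent_heat(ta):
    """Latent heat of vaporization, J kg-1 (weak linear dependence on ta)."""
    ta = np.asarray(ta, dtype=float)
    return (2.501 - 0.00237 * ta) * 1e6


def psychrometric_constant(ta, pa):
    """Psychrometric constant gamma = cp*PA/(eps*lambda), kPa K-1."""
    return CP * np.asarray(pa, dtype=float) / (EPS * latent_heat(ta))


def air_density(ta, pa):
    """Moist-air density from the ideal-gas law (dry-air approximation), kg m-3."""
    return np.asarray(pa, dtype=float) * 1000.0 / (RD * (np.asarray(ta, dtype=float) + 273.15))


def pressure_from_elevation(elev_m):
    """Barometric estimate of surface pressure (kPa) from elevation (m)."""
    return P0 * (1.0 - 0.0065 * np.asarray(elev_m, dtype=float) / 288.15) ** 5.2553


def aerodynamic_conductance(ws, ustar):
    """Aerodynamic conductance for heat, m s-1 (Thom-type empirical form).

    Ga = (WS/u*^2 + 6.2 u*^-0.67)^-1.  Both inputs must be positive.
    """
    ws = np.asarray(ws, dtype=float)
    ustar = np.asarray(ustar, dtype=float)
    if np.any(ws[~np.isnan(ws)] <= 0) or np.any(ustar[~np.isnan(ustar)] <= 0):
        raise ValueError("wind speed and friction velocity must be positive")
    return 1.0 / (ws / ustar**2 + 6.2 * ustar**-0.67)


def penman_monteith_le(gs, ga, available_energy, ta, vpd, pa):
    """Forward Penman–Monteith latent heat flux (W m-2) at surface conductance gs."""
    delta = esat_slope(ta)
    gamma = psychrometric_constant(ta, pa)
    rho = air_density(ta, pa)
    num = delta * available_energy + rho * CP * ga * vpd
    return num / (delta + gamma * (1.0 + ga / gs))


def surface_conductance(le, h, ta, vpd, pa, ga):
    """Invert Penman–Monteith for the surface conductance Gs (m s-1).

    Available energy is approximated by A = H + LE.  Records with VPD <= 0,
    a non-positive denominator, or Gs <= 0 come back NaN (physically invalid
    inversions are screened, not propagated).  LE = 0 maps to Gs = 0.
    """
    le = np.asarray(le, dtype=float)
    h = np.asarray(h, dtype=float)
    vpd = np.asarray(vpd, dtype=float)
    delta = esat_slope(ta)
    gamma = psychrometric_constant(ta, pa)
    rho = air_density(ta, pa)
    a = h + le
    denom = delta * a + rho * CP * np.asarray(ga, dtype=float) * vpd - le * (delta + gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        gs = le * gamma * np.asarray(ga, dtype=float) / denom
    gs = np.where(le == 0, 0.0, gs)
    bad = (vpd <= 0) | (denom <= 0) | (gs < 0)
    return np.where(bad, np.nan, gs)
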