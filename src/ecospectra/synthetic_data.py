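"""Forward simulators with known ground truth for every pipeline stage.

Three generators mirror the three kinds of input the pipeline consumes:

* :func:`simulate_site` — a half-hourly flux-tower record built from a
  saturating light response, Q10 respiration, and Penman–Monteith (or fixed
  Bowen ratio) energy partitioning, with the analytic site-level property
  values recorded in :class:`GroundTruth`;
* :func:`simulate_community` — a species abundance/trait table with known
  community-weighted means;
* :func:`simulate_efp_matrix` — site x variable matrices drawn from an
  explicit low-rank latent factor model, for exercising the ordination stage.

All randomness flows from a single seed; the same scenario and seed give a
bit-identical realization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import meteo
from .flux_io import FluxSeries, SiteMeta
from .preprocess import (FilterConfig, growing_season_mask, precip_exclusion_mask,
                         quality_mask, radiation_mask, ustar_mask)

#: conversion from shortwave irradiance (W m-2) to PPFD (umol m-2 s-1)
SW_TO_PPFD = 2.11
#: mmol H2O per mm of water column per m2 (molar mass 18.015 g mol-1)
MMOL_PER_MM = 55_508.0


def light_response(ppfd, alpha, beta):
    """Rectangular-hyperbola GPP (umol CO2 m-2 s-1) at the given PPFD."""
    ppfd = np.asarray(ppfd, dtype=float)
    return alpha * ppfd * beta / (alpha * ppfd + beta)


@dataclass
class SiteScenario:
    """Everything that defines one simulated site.

    The flux parameters are typical of a productive temperate site: an
    apparent quantum yield ``alpha`` of 0.05 umol CO2 per umol photons, an
    asymptotic canopy assimilation ``beta`` of 40 umol CO2 m-2 s-1, basal
    respiration 2 umol m-2 s-1 at 15 degC with Q10 = 2, and a prescribed
    surface conductance of 12 mm s-1.  Noise scales are additive Gaussian
    standard deviations per flux; set them (and the QC corruption fractions)
    to zero for a noiseless realization.
    """

    n_years: int = 1
    latitude: float = 45.0
    elevation: float = 100.0
    alpha: float = 0.05            # umol CO2 / umol photons
    beta: float = 40.0             # umol CO2 m-2 s-1
    rbase: float = 2.0             # umol CO2 m-2 s-1 at 15 degC
    q10: float = 2.0
    gs_true: float = 0.012         # m s-1
    energy_mode: str = "pm"        # "pm" or "bowen"
    evaporative_fraction: float = 0.5   # used in "bowen" mode
    available_energy_fraction: float = 0.65  # A = f * SWin
    transpiration_fraction: float = 0.65     # T = f * ET
    sw_transmissivity: float = 0.75
    precip_events_per_day: float = 0.10
    precip_mean_depth: float = 3.0       # mm per event
    gpp_noise: float = 1.5         # umol m-2 s-1
    le_noise: float = 15.0         # W m-2
    h_noise: float = 15.0          # W m-2
    sw_noise: float = 0.15         # sd of the cloud transmissivity factor
    ta_noise: float = 0.5          # degC
    qc_bad_fraction: float = 0.10
    qc_gapfill_fraction: float = 0.20
    step_minutes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "rbase", "q10", "gs_true"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gpp_noise", "le_noise", "h_noise", "sw_noise", "ta_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.energy_mode not in ("pm", "bowen"):
            raise ValueError("energy_mode must be 'pm' or 'bowen'")

    def noiseless(self) -> "SiteScenario":
        """Copy with every stochastic corruption switched off."""
        return replace(self, gpp_noise=0.0, le_noise=0.0, h_noise=0.0,
                       sw_noise=0.0, ta_noise=0.0, qc_bad_fraction=0.0,
                       precip_events_per_day=0.0)


@dataclass
class GroundTruth:
    """Analytic property values a perfect pipeline should recover."""

    gppsat_true: float | None = None
    recomax_true: float | None = None
    ef_true: float | None = None
    gsmax_true: float | None = None
    wuet_true: float | None = None
    cwm_true: dict[str, float] = field(default_factory=dict)
    coverage: float | None = None


def _solar_cycle(index: pd.DatetimeIndex, latitude: float) -> np.ndarray:
    """Clipped-sinusoid potential shortwave radiation (W m-2)."""
    doy = index.dayofyear.to_numpy()
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (doy - 81) / 365.0)
    lat = np.deg2rad(latitude)
    hour_angle = np.pi * (hour - 12.0) / 12.0
    sin_elev = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hour_angle)
    return 1100.0 * np.clip(sin_elev, 0.0, None)


def simulate_site(scenario: SiteScenario,
                  cfg: FilterConfig | None = None,
                  site_id: str = "SYN-001",
                  ) -> tuple[FluxSeries, SiteMeta, GroundTruth]:
    """Simulate one flux-tower record and the properties encoded in it.

    The noise-free forward model is built first; the site-level ground truth
    is derived from it (analytically where possible: the light-response value
    at PPFD 2000 for GPPsat, the prescribed conductance for Gsmax, the
    prescribed Bowen partitioning for EF), then Gaussian noise, precipitation
    events, and QC-flag corruption are layered on top.
    """
    cfg = cfg or FilterConfig()
    rng = np.random.default_rng(scenario.seed)
    index = pd.date_range("2001-01-01 00:00", periods=scenario.n_years * 365 * (1440 // scenario.step_minutes),
                          freq=f"{scenario.step_minutes}min", name="timestamp")
    dt = scenario.step_minutes * 60.0
    hour = index.hour.to_numpy() + index.minute.to_numpy() / 60.0
    doy = index.dayofyear.to_numpy()

    sw_pot = _solar_cycle(index, scenario.latitude)
    season = np.cos(2 * np.pi * (doy - 200) / 365.0) * np.sign(scenario.latitude)
    ta_clean = 10.0 + 8.0 * season + 5.0 * np.sin(np.pi * (hour - 8.0) / 12.0) * (sw_pot > 0)
    rh = np.clip(0.55 + 0.20 * np.cos(2 * np.pi * (hour - 4.0) / 24.0), 0.2, 0.98)
    pa = float(meteo.pressure_from_elevation(scenario.elevation))

    sw_clean = scenario.sw_transmissivity * sw_pot
    ppfd = SW_TO_PPFD * sw_clean
    gpp_clean = light_response(ppfd, scenario.alpha, scenario.beta)
    reco_clean = scenario.rbase * scenario.q10 ** ((ta_clean - 15.0) / 10.0)

    vpd_clean = np.maximum(meteo.esat(ta_clean) * (1.0 - rh), 1e-3)
    ustar = np.clip(0.35 + 0.15 * sw_clean / 1000.0, 0.05, None)
    ws = np.clip(2.0 + sw_clean / 500.0, 0.1, None)
    avail = scenario.available_energy_fraction * sw_clean
    if scenario.energy_mode == "bowen":
        le_clean = scenario.evaporative_fraction * avail
        h_clean = (1.0 - scenario.evaporative_fraction) * avail
    else:
        ga = meteo.aerodynamic_conductance(ws, ustar)
        le_clean = meteo.penman_monteith_le(scenario.gs_true, ga, avail,
                                            ta_clean, vpd_clean, pa)
        le_clean = np.where(avail > 0, le_clean, 0.0)
        h_clean = avail - le_clean
    et_mm = np.clip(le_clean, 0.0, None) / meteo.latent_heat(ta_clean) * dt  # kg m-2 = mm
    t_mm = scenario.transpiration_fraction * et_mm

    # precipitation: Bernoulli event starts, exponential depths
    steps_per_day = 1440 // scenario.step_minutes
    p_event = rng.random(len(index)) < scenario.precip_events_per_day / steps_per_day
    precip = np.where(p_event, rng.exponential(scenario.precip_mean_depth, len(index)), 0.0)

    clean = pd.DataFrame({
        "NEE": reco_clean - gpp_clean, "GPP": gpp_clean, "RECO": reco_clean,
        "LE": le_clean, "H": h_clean, "SWin": sw_clean, "SWin_pot": sw_pot,
        "Ta": ta_clean, "VPD": vpd_clean, "P": precip, "ustar": ustar,
        "WS": ws, "PA": pa, "T": t_mm, "NEE_QC": 0.0,
    }, index=index)
    truth = _ground_truth(scenario, FluxSeries(clean.copy()), cfg, dt)

    # layer stochastic corruption on the clean record
    trans = np.clip(scenario.sw_transmissivity + scenario.sw_noise * rng.standard_normal(len(index)),
                    0.05, 1.0)
    sw = trans * sw_pot
    gpp = np.clip(light_response(SW_TO_PPFD * sw, scenario.alpha, scenario.beta)
                  + scenario.gpp_noise * rng.standard_normal(len(index)), 0.0, None)
    ta = ta_clean + scenario.ta_noise * rng.standard_normal(len(index))
    reco = np.clip(scenario.rbase * scenario.q10 ** ((ta - 15.0) / 10.0)
                   + 0.25 * scenario.gpp_noise * rng.standard_normal(len(index)), 0.0, None)
    le = le_clean + scenario.le_noise * rng.standard_normal(len(index))
    h = h_clean + scenario.h_noise * rng.standard_normal(len(index))

    qc = np.zeros(len(index))
    qc[rng.random(len(index)) < scenario.qc_gapfill_fraction] = 1.0
    qc[rng.random(len(index)) < scenario.qc_bad_fraction] = 2.0

    noisy = clean.copy()
    noisy["SWin"], noisy["GPP"], noisy["Ta"], noisy["RECO"] = sw, gpp, ta, reco
    noisy["NEE"] = reco - gpp
    noisy["LE"], noisy["H"] = le, h
    noisy["VPD"] = np.maximum(meteo.esat(ta) * (1.0 - rh), 1e-3)
    noisy["NEE_QC"] = qc

    meta = SiteMeta(site_id=site_id, igbp="ENF", latitude=scenario.latitude,
                    longitude=0.0, elevation=scenario.elevation, hc=15.0, lai_max=4.0,
                    years=sorted(set(index.year)))
    return FluxSeries(noisy), meta, truth


def _ground_truth(scenario: SiteScenario, clean: FluxSeries,
                  cfg: FilterConfig, dt: float) -> GroundTruth:
    """Site-level truth from the noise-free forward series."""
    season = growing_season_mask(clean, cfg)
    gppsat = light_response(2000.0, scenario.alpha, scenario.beta)

    night = season & radiation_mask(clean, cfg.nighttime_swin_max, "night")
    nee_night = clean.NEE[night].dropna()
    recomax = float(np.percentile(nee_night, 90)) if len(nee_night) else None

    energy_keep = (precip_exclusion_mask(clean, cfg)
                   & radiation_mask(clean, cfg.ef_swin_min, "day")
                   & ustar_mask(clean, cfg))
    if cfg.apply_growing_season_to_energy:
        energy_keep &= season
    if scenario.energy_mode == "bowen":
        ef = scenario.evaporative_fraction
    else:
        le, hh = clean.LE[energy_keep], clean.H[energy_keep]
        ok = (le + hh) > 0
        ef = float(np.median(le[ok] / (le[ok] + hh[ok]))) if ok.any() else None

    gsmax = scenario.gs_true if scenario.energy_mode == "pm" else None

    day_pot = radiation_mask(clean, cfg.wue_swinpot_min, "day_pot") & season
    gpp_sum = float((clean.GPP[day_pot] * dt).sum())
    t_sum = float(clean.T[day_pot].sum())
    wuet = gpp_sum / (t_sum * MMOL_PER_MM) if t_sum > 0 else None

    return GroundTruth(gppsat_true=float(gppsat), recomax_true=recomax,
                       ef_true=ef, gsmax_true=gsmax, wuet_true=wuet)


# ---------------------------------------------------------------------------
# community tables

#: default log-normal trait distributions: (median, sigma of log)
DEFAULT_TRAIT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "LL": (12.0, 0.6),       # months
    "LMA": (0.08, 0.4),      # mg mm-2
    "Nmass": (2.0, 0.3),     # % dry mass
    "SSD": (0.55, 0.25),     # g cm-3
}


def simulate_community(n_species: int,
                       abundance_concentration: float = 2.0,
                       trait_distributions: Mapping[str, tuple[float, float]] | None = None,
                       seed: int = 0,
                       coverage: float = 1.0,
                       ) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a species abundance/trait table with known community-weighted means.

    Relative abundances come from a symmetric Dirichlet and are scaled so
    known cover sums to ``coverage`` (<= 1); the true CWM of each trait is
    the relative-abundance-weighted mean, independent of the coverage scale.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    dists = dict(DEFAULT_TRAIT_DISTRIBUTIONS)
    if trait_distributions:
        dists.update(trait_distributions)
    rng = np.random.default_rng(seed)
    rel = rng.dirichlet(np.full(n_species, abundance_concentration))
    table = pd.DataFrame({"species": [f"sp{i + 1}" for i in range(n_species)],
                          "cover": rel * coverage})
    truth = GroundTruth(coverage=coverage)
    for trait, (median, sigma) in dists.items():
        vals = median * np.exp(sigma * rng.standard_normal(n_species))
        table[trait] = vals
        truth.cwm_true[trait] = float(np.sum(rel * vals))
    return table, truth


# ---------------------------------------------------------------------------
# latent-model site x variable matrices

def simulate_efp_matrix(n_sites: int,
                        latent_loadings: pd.DataFrame | np.ndarray,
                        noise_sd: float | np.ndarray = 0.0,
                        seed: int = 0) -> pd.DataFrame:
    """Draw a site x variable matrix from a rank-k linear factor model.

    X = F L' + E with standard-normal factors F (n x k), loadings L (p x k),
    and independent Gaussian noise E (scalar or per-variable sd).
    """
    if isinstance(latent_loadings, pd.DataFrame):
        columns = list(latent_loadings.index)
        load = latent_loadings.to_numpy(dtype=float)
    else:
        load = np.asarray(latent_loadings, dtype=float)
        columns = [f"v{j + 1}" for j in range(load.shape[0])]
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((n_sites, load.shape[1]))
    noise = np.atleast_1d(np.asarray(noise_sd, dtype=float))
    x = factors @ load.T + rng.standard_normal((n_sites, load.shape[0])) * noise
    return pd.DataFrame(x, columns=columns,
                        index=[f"site{i + 1}" for i in range(n_sites)])


#: isotropic noise sd that pairs with :func:`leaf_economics_like_loadings`
LEAF_ECONOMICS_NOISE_SD = 0.5719


def leaf_economics_like_loadings() -> pd.DataFrame:
    """A rank-2 latent loading pattern with the leaf-economics sign structure.

    Axis 1 opposes nitrogen content, photosynthetic capacity and respiration
    to leaf mass per area and leaf longevity (the published first-axis
    correlations of the five-variable ecosystem economics spectrum); axis 2
    is a weaker orthogonal axis on which every variable except wNmass shares
    a sign.  With isotropic noise of sd :data:`LEAF_ECONOMICS_NOISE_SD`, the
    population correlation-matrix PCA of the generated data puts 59.2% of
    the variance on the first component and 82.3% on the first two.
    """
    return pd.DataFrame(
        {"axis1": [0.85, 0.79, 0.69, -0.83, -0.67],
         "axis2": [-0.0843, 0.4629, 0.5484, 0.3610, 0.5565]},
        index=["wNmass", "GPPsat", "RECOmax", "wLMA", "wLL"])


def residual_noise_sd(loadings: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Per-variable noise sd that brings each variable's variance to 1."""
    load = loadings.to_numpy() if isinstance(loadings, pd.DataFrame) else np.asarray(loadings)
    resid = 1.0 - (load ** 2).sum(axis=1)
    if (resid < 0).any():
        raise ValueError("loadings imply variance > 1 for some variable")
    return np.sqrt(resid)
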