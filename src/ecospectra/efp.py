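"""Ecosystem functional properties from the filtered half-hourly record.

Six site-level scalars are derived:

GPPsat   photosynthetic capacity: the rectangular-hyperbola light response
         fitted in 5-day moving windows, evaluated at PPFD = 2000
         umol m-2 s-1; per-year 95th percentiles averaged over years.
RECOmax  90th percentile of night-time NEE (maximum ecosystem respiration).
EF       median evaporative fraction LE/(LE+H) over rain-free, daytime,
         well-mixed records.
Gsmax    90th percentile of the surface conductance from the inverted
         Penman-Monteith equation.
WUEt     cumulative GPP over cumulative transpiration (umol CO2 / mmol H2O).
PNUE     GPPsat per unit canopy nitrogen, GPPsat / (wNarea * LAImax).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import meteo
from .flux_io import FluxSeries, SiteMeta
from .preprocess import (FilterConfig, growing_season_mask, precip_exclusion_mask,
                         quality_mask, radiation_mask, ustar_mask)
from .synthetic_data import SW_TO_PPFD, MMOL_PER_MM, light_response

logger = logging.getLogger(__name__)

#: saturating photon flux density at which GPPsat is evaluated, umol m-2 s-1
PPFD_SAT = 2000.0


class LightResponseCurve:
    """Rectangular-hyperbola light-response model for one fitting window.

    GPP = alpha * PPFD * beta / (alpha * PPFD + beta), PPFD = 2.11 * SWin.

    Parameters
    ----------
    gpp : array of GPP (umol CO2 m-2 s-1), daytime records only
    swin : array of incoming shortwave radiation (W m-2)
    """

    def __init__(self, gpp, swin):
        gpp = np.asarray(gpp, dtype=float)
        swin = np.asarray(swin, dtype=float)
        ok = np.isfinite(gpp) & np.isfinite(swin)
        self.gpp = gpp[ok]
        self.ppfd = SW_TO_PPFD * swin[ok]
        self.nobs = int(ok.sum())

    def fit(self, alpha0: float = 0.02, beta0: float | None = None) -> "LightResponseResults":
        """Nonlinear least squares; non-convergence yields a non-converged result."""
        if beta0 is None:
            beta0 = float(np.clip(self.gpp.max(initial=1.0), 1.0, 100.0))
        try:
            popt, pcov = curve_fit(
                light_response, self.ppfd, self.gpp,
                p0=(alpha0, beta0), bounds=((1e-8, 1e-8), (0.5, 100.0)),
                maxfev=2000)
            bse = np.sqrt(np.diag(pcov))
            converged = np.all(np.isfinite(popt))
        except (RuntimeError, ValueError):
            popt, bse, converged = (np.nan, np.nan), (np.nan, np.nan), False
        return LightResponseResults(self, float(popt[0]), float(popt[1]),
                                    float(bse[0]), float(bse[1]), bool(converged))


@dataclass
class LightResponseResults:
    """Fitted light-response parameters for one window."""

    model: LightResponseCurve
    alpha: float
    beta: float
    alpha_se: float
    beta_se: float
    converged: bool

    @property
    def gppsat(self) -> float:
        """Fitted GPP at the saturating PPFD of 2000 umol m-2 s-1."""
        return float(light_response(PPFD_SAT, self.alpha, self.beta))

    def predict(self, swin) -> np.ndarray:
        return light_response(SW_TO_PPFD * np.asarray(swin, dtype=float),
                              self.alpha, self.beta)

    def summary(self) -> str:
        lines = ["Light response curve (rectangular hyperbola)",
                 f"  n obs      {self.model.nobs:>10d}",
                 f"  alpha      {self.alpha:>10.4f}  (se {self.alpha_se:.4f})",
                 f"  beta       {self.beta:>10.3f}  (se {self.beta_se:.3f})",
                 f"  GPPsat     {self.gppsat:>10.3f}",
                 f"  converged  {str(self.converged):>10s}"]
        return "\n".join(lines)


def fit_light_response(window: pd.DataFrame, cfg: FilterConfig | None = None,
                       ) -> LightResponseResults | None:
    """Fit one 5-day window (columns GPP, SWin); None if too few points."""
    cfg = cfg or FilterConfig()
    model = LightResponseCurve(window["GPP"].to_numpy(), window["SWin"].to_numpy())
    if model.nobs < cfg.min_window_points:
        return None
    res = model.fit()
    return res if res.converged else None


def gppsat_site(series: FluxSeries, cfg: FilterConfig | None = None) -> float:
    """Site GPPsat: mean over years of the yearly 95th percentile of window fits.

    Window estimates above the 60 umol m-2 s-1 cap are excluded (not clipped).
    """
    cfg = cfg or FilterConfig()
    keep = (quality_mask(series, cfg) & growing_season_mask(series, cfg)
            & radiation_mask(series, cfg.daytime_swin_min, "day"))
    day = series.data.loc[keep, ["GPP", "SWin"]].dropna()
    if day.empty:
        return float("nan")
    estimates: list[tuple[int, float]] = []
    half = pd.Timedelta(days=(cfg.window_days - 1) / 2)
    for center in pd.DatetimeIndex(day.index.normalize().unique()):
        window = day.loc[center - half: center + half + pd.Timedelta(days=1) - pd.Timedelta(seconds=1)]
        res = fit_light_response(window, cfg)
        if res is not None:
            estimates.append((center.year, res.gppsat))
    if not estimates:
        return float("nan")
    return aggregate_gppsat(pd.DataFrame(estimates, columns=["year", "gppsat"]), cfg)


def aggregate_gppsat(estimates: pd.DataFrame, cfg: FilterConfig | None = None) -> float:
    """Site GPPsat from per-window estimates (columns ``year``, ``gppsat``).

    Estimates above the cap are excluded (not clipped); the yearly 95th
    percentiles (linear interpolation) are averaged over years.
    """
    cfg = cfg or FilterConfig()
    est = estimates[estimates["gppsat"] <= cfg.gppsat_cap]
    if est.empty:
        return float("nan")
    yearly = est.groupby("year")["gppsat"].quantile(0.95)
    return float(yearly.mean())


def recomax_site(series: FluxSeries, cfg: FilterConfig | None = None) -> float:
    """90th percentile of quality-screened, in-season night-time NEE."""
    cfg = cfg or FilterConfig()
    keep = (quality_mask(series, cfg) & growing_season_mask(series, cfg)
            & radiation_mask(series, cfg.nighttime_swin_max, "night"))
    nee = series.NEE[keep].dropna()
    n_neg = int((nee < 0).sum())
    if n_neg:
        logger.info("recomax_site: %d negative night-time NEE records used as-is", n_neg)
    if nee.empty:
        return float("nan")
    return float(np.percentile(nee, 90))


def _energy_keep(series: FluxSeries, cfg: FilterConfig) -> pd.Series:
    keep = (quality_mask(series, cfg)
            & precip_exclusion_mask(series, cfg)
            & radiation_mask(series, cfg.ef_swin_min, "day")
            & ustar_mask(series, cfg))
    if cfg.apply_growing_season_to_energy:
        keep &= growing_season_mask(series, cfg)
    return keep


def ef_site(series: FluxSeries, cfg: FilterConfig | None = None) -> float:
    """Median evaporative fraction LE/(LE+H); records with LE+H <= 0 skipped."""
    cfg = cfg or FilterConfig()
    keep = _energy_keep(series, cfg)
    le, h = series.LE[keep], series.H[keep]
    ok = (le + h) > 0
    ef = le[ok] / (le[ok] + h[ok])
    ef = ef.dropna()
    return float(ef.median()) if len(ef) else float("nan")


def gsmax_site(series: FluxSeries, cfg: FilterConfig | None = None,
               elevation: float | None = None) -> float:
    """90th percentile of the Penman-Monteith surface conductance (m s-1).

    Uses the EF filter set plus exclusion of non-positive VPD; records whose
    inversion is physically invalid are dropped.  When surface pressure is
    missing it is estimated from elevation via the barometric formula.
    """
    cfg = cfg or FilterConfig()
    keep = _energy_keep(series, cfg) & (series.VPD > 0)
    d = series.data.loc[keep, ["LE", "H", "Ta", "VPD", "PA", "WS", "ustar"]].dropna(
        subset=["LE", "H", "Ta", "VPD", "WS", "ustar"])
    d = d[(d["WS"] > 0) & (d["ustar"] > 0)]
    if d.empty:
        return float("nan")
    pa = d["PA"].to_numpy()
    if np.isnan(pa).any():
        if elevation is None:
            logger.warning("gsmax_site: missing PA and no elevation; using sea level")
            elevation = 0.0
        pa = np.where(np.isnan(pa), meteo.pressure_from_elevation(elevation), pa)
    ga = meteo.aerodynamic_conductance(d["WS"].to_numpy(), d["ustar"].to_numpy())
    gs = meteo.surface_conductance(d["LE"].to_numpy(), d["H"].to_numpy(),
                                   d["Ta"].to_numpy(), d["VPD"].to_numpy(), pa, ga)
    gs = gs[np.isfinite(gs)]
    if gs.size == 0:
        return float("nan")
    return float(np.percentile(gs, 90))


def wuet_site(series: FluxSeries, cfg: FilterConfig | None = None) -> float:
    """Transpiration-based water-use efficiency, umol CO2 / mmol H2O.

    Day-time records (SWin_pot > 200 W m-2) are aggregated to daily GPP and
    T totals; days with a good-quality fraction <= 0.8 are dropped, as are
    days whose GPP/T ratio exceeds the site mean by 3 standard deviations.
    WUEt is the ratio of the summed GPP to the summed transpiration.
    """
    cfg = cfg or FilterConfig()
    if series.T.notna().sum() == 0:
        return float("nan")
    keep = radiation_mask(series, cfg.wue_swinpot_min, "day_pot")
    if cfg.apply_growing_season_to_energy:
        keep &= growing_season_mask(series, cfg)
    d = series.data.loc[keep, ["GPP", "T", "NEE_QC"]]
    if d.empty:
        return float("nan")
    day = d.index.normalize()
    good = quality_mask(series, cfg)[keep]
    daily = pd.DataFrame({
        "gpp": (d["GPP"] * series.step_seconds).groupby(day).sum(min_count=1),
        "t": d["T"].groupby(day).sum(min_count=1),
        "quality": good.groupby(day).mean(),
    }).dropna()
    daily = daily[daily["quality"] > cfg.daily_quality_fraction]
    daily = daily[daily["t"] > 0]
    if daily.empty:
        return float("nan")
    ratio = daily["gpp"] / daily["t"]
    cap = ratio.mean() + cfg.outlier_sd_multiplier * ratio.std(ddof=1)
    if np.isfinite(cap):
        daily = daily[ratio <= cap]
    t_total = daily["t"].sum()
    if t_total <= 0:
        return float("nan")
    return float(daily["gpp"].sum() / (t_total * MMOL_PER_MM))


def pnue(gppsat: float, wnarea: float, lai_max: float) -> float:
    """Photosynthetic nitrogen use-efficiency GPPsat/(wNarea*LAImax), umol CO2 gN-1 s-1."""
    if not (wnarea and wnarea > 0) or not (lai_max and lai_max > 0) or not np.isfinite(gppsat):
        logger.info("pnue: non-positive or missing inputs -> missing")
        return float("nan")
    return gppsat / (wnarea * lai_max)


def mean_annual_temperature(series: FluxSeries, cfg: FilterConfig | None = None) -> float:
    """Mean over years of the yearly mean quality-screened, in-season Ta (degC)."""
    cfg = cfg or FilterConfig()
    keep = quality_mask(series, cfg) & growing_season_mask(series, cfg)
    ta = series.Ta[keep].dropna()
    if ta.empty:
        return float("nan")
    return float(ta.groupby(ta.index.year).mean().mean())


@dataclass
class EFPRecord:
    """One row of the site x property table fed to the ordination stage."""

    site_id: str
    GPPsat: float = float("nan")
    RECOmax: float = float("nan")
    EF: float = float("nan")
    Gsmax: float = float("nan")
    WUEt: float = float("nan")
    PNUE: float = float("nan")
    Ta: float = float("nan")
    wLL: float = float("nan")
    wLMA: float = float("nan")
    wNmass: float = float("nan")
    wNarea: float = float("nan")
    wSSD: float = float("nan")
    Hc: float = float("nan")
    LAImax: float = float("nan")
    IGBP: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def compute_efps(series: FluxSeries, meta: SiteMeta,
                 cfg: FilterConfig | None = None,
                 community_traits: dict | None = None) -> EFPRecord:
    """Derive all flux-based properties for one site; merge trait CWMs if given."""
    cfg = cfg or FilterConfig()
    rec = EFPRecord(site_id=meta.site_id, IGBP=meta.igbp,
                    Hc=meta.hc if meta.hc is not None else float("nan"),
                    LAImax=meta.lai_max if meta.lai_max is not None else float("nan"))
    rec.GPPsat = gppsat_site(series, cfg)
    rec.RECOmax = recomax_site(series, cfg)
    rec.EF = ef_site(series, cfg)
    rec.Gsmax = gsmax_site(series, cfg, elevation=meta.elevation)
    rec.WUEt = wuet_site(series, cfg)
    rec.Ta = mean_annual_temperature(series, cfg)
    if community_traits:
        for key in ("wLL", "wLMA", "wNmass", "wNarea", "wSSD"):
            if key in community_traits and community_traits[key] is not None:
                setattr(rec, key, float(community_traits[key]))
    rec.PNUE = pnue(rec.GPPsat, rec.wNarea, rec.LAImax)
    return rec
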