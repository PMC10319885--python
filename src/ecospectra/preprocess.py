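"""Record-level filters applied to the flux series before any property is derived.

Every threshold is carried in :class:`FilterConfig` so that a run manifest can
echo the exact filtering used.  All masks are pure boolean functions of the
series and the config: conjunction order never matters, and a missing input
value is always conservative (record excluded) unless stated otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .flux_io import FluxSeries

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds of the record-level quality screen.

    Defaults are the values used throughout the analysis: NEE quality flags 0
    (measured) and 1 (good gap-fill) are retained; the growing season is the
    set of days whose daily GPP exceeds the minimum by 30% of the annual
    daily-GPP range; day/night splits use shortwave radiation; rain events
    (P >= 0.1 mm) exclude the following 48 h; friction velocity must exceed
    0.20 m s-1.
    """

    qc_keep: tuple[int, ...] = (0, 1)
    growing_season_fraction: float = 0.30
    growing_season_smooth_days: int = 15
    growing_season_scope: str = "site_year"   # or "pooled"
    daytime_swin_min: float = 100.0           # W m-2, GPPsat stream
    nighttime_swin_max: float = 50.0          # W m-2, RECOmax stream
    ef_swin_min: float = 200.0                # W m-2, EF/Gsmax stream
    wue_swinpot_min: float = 200.0            # W m-2, WUEt stream
    precip_event_min: float = 0.1             # mm per interval
    precip_exclusion_hours: float = 48.0
    ustar_min: float = 0.20                   # m s-1
    gppsat_cap: float = 60.0                  # umol CO2 m-2 s-1
    daily_quality_fraction: float = 0.8
    outlier_sd_multiplier: float = 3.0
    min_window_points: int = 20
    window_days: int = 5
    apply_growing_season_to_energy: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.growing_season_fraction < 1:
            raise ValueError("growing_season_fraction must be in (0,1)")
        for name in ("daytime_swin_min", "nighttime_swin_max", "ef_swin_min",
                     "wue_swinpot_min", "precip_event_min", "precip_exclusion_hours",
                     "ustar_min", "gppsat_cap", "daily_quality_fraction",
                     "outlier_sd_multiplier"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)


def quality_mask(series: FluxSeries, cfg: FilterConfig) -> pd.Series:
    """True where the NEE quality flag is in the retained set (missing -> False)."""
    qc = series.NEE_QC
    return qc.isin(cfg.qc_keep) & qc.notna()


def growing_season_mask(series: FluxSeries, cfg: FilterConfig) -> pd.Series:
    """True on days within the active growing season.

    Daily mean GPP is smoothed with a centered moving average
    (``growing_season_smooth_days``, min_periods=1); a day is in season iff
    its smoothed value strictly exceeds ``min + f*(max - min)`` of the
    smoothed series, computed per site-year (default) or pooled.  When
    max == min the rule is vacuous and every day is retained.
    """
    gpp = series.GPP
    if gpp.notna().sum() == 0:
        raise ValueError("growing_season_mask requires at least one GPP value")
    daily = gpp.groupby(series.index.normalize()).mean()

    def _season(d: pd.Series) -> pd.Series:
        sm = d.rolling(cfg.growing_season_smooth_days, center=True, min_periods=1).mean()
        lo, hi = sm.min(), sm.max()
        if hi == lo:
            return pd.Series(True, index=d.index)
        thr = lo + cfg.growing_season_fraction * (hi - lo)
        return sm > thr

    if cfg.growing_season_scope == "site_year":
        in_season = daily.groupby(daily.index.year, group_keys=False).apply(_season)
    else:
        in_season = _season(daily)
    return pd.Series(in_season.reindex(series.index.normalize()).to_numpy(),
                     index=series.index).fillna(False)


def precip_exclusion_mask(series: FluxSeries, cfg: FilterConfig) -> pd.Series:
    """False for every interval with P >= 0.1 mm and for the following 48 h.

    Windows from overlapping events are unioned.  If P is entirely absent the
    mask is all-true and a prominent warning is logged (rain screening is
    applied "where available").
    """
    p = series.P
    if p.notna().sum() == 0:
        logger.warning("precipitation column absent/empty: rain exclusion NOT applied")
        return pd.Series(True, index=series.index)
    events = (p >= cfg.precip_event_min).to_numpy()
    n_after = int(round(cfg.precip_exclusion_hours * 3600 / series.step_seconds))
    excluded = np.zeros(len(series), dtype=bool)
    for i in np.flatnonzero(events):
        excluded[i:i + n_after + 1] = True
    return pd.Series(~excluded, index=series.index)


def ustar_mask(series: FluxSeries, cfg: FilterConfig) -> pd.Series:
    """True iff friction velocity strictly exceeds the threshold (0.20 m s-1)."""
    u = series.ustar
    return (u > cfg.ustar_min).fillna(False)


def radiation_mask(series: FluxSeries, threshold: float, mode: str) -> pd.Series:
    """Day/night selection on shortwave radiation.

    mode "day":     retain SWin  > threshold   (daytime records)
    mode "night":   retain SWin  < threshold   (night-time records)
    mode "day_pot": retain SWin_pot > threshold (potential-radiation daytime)
    """
    if mode == "day":
        return (series.SWin > threshold).fillna(False)
    if mode == "night":
        return (series.SWin < threshold).fillna(False)
    if mode == "day_pot":
        return (series.SWin_pot > threshold).fillna(False)
    raise ValueError(f"unknown radiation mask mode {mode!r}")
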