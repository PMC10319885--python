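"""Community-weighted mean traits from species abundance tables.

A community table has one row per species with a fractional cover (share of
site area, summing to <= 1 over the species with known abundance) and the
leaf/stem traits LL (months), LMA (mg mm-2), Nmass (% dry mass) and SSD
(g cm-3).  Sites where the known cover sums to less than half the site area
are rejected outright; species with unknown abundance share the residual
cover equally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ("LL", "LMA", "Nmass", "SSD")


def _known_cover(table: pd.DataFrame) -> float:
    return float(table["cover"].dropna().sum())


def fill_unknown_abundances(table: pd.DataFrame) -> pd.DataFrame:
    """Split the residual cover equally among species with unknown abundance.

    Known covers are untouched; with no unknown species the table is returned
    unchanged.  Raises if the known covers already exceed 1.
    """
    if len(table) < 1:
        raise ValueError("community table must contain at least one species")
    known = _known_cover(table)
    if known > 1 + 1e-12:
        raise ValueError(f"known covers sum to {known:.3f} > 1")
    out = table.copy()
    unknown = out["cover"].isna()
    if unknown.any():
        out.loc[unknown, "cover"] = (1.0 - known) / int(unknown.sum())
    return out


def check_coverage(table: pd.DataFrame, threshold: float = 0.5) -> bool:
    """Accept the site iff the summed known species cover is not below threshold."""
    return _known_cover(table) >= threshold


def cwm(table: pd.DataFrame, trait: str) -> float:
    """Cover-weighted mean of one trait.

    Species missing the trait are dropped and the weights renormalized over
    the remainder (traits come from heterogeneous sources, so availability
    differs per trait).  Missing entirely -> NaN.
    """
    sub = table[["cover", trait]].dropna()
    if sub.empty or sub["cover"].sum() <= 0:
        return float("nan")
    if len(sub) < len(table):
        logger.info("cwm(%s): %d/%d species lack the trait; weights renormalized",
                    trait, len(table) - len(sub), len(table))
    return float(np.average(sub[trait], weights=sub["cover"]))


def wnarea(wnmass: float, wlma: float) -> float:
    """Canopy nitrogen per leaf area, g N m-2: (Nmass %/100) * (LMA mg mm-2 * 1000)."""
    if not (wnmass is not None and np.isfinite(wnmass)) or not (wlma and np.isfinite(wlma)):
        return float("nan")
    if wnmass < 0 or wlma <= 0:
        return float("nan")
    return (wnmass / 100.0) * (wlma * 1000.0)


def community_traits(table: pd.DataFrame, coverage_threshold: float = 0.5) -> dict:
    """All community-weighted means for one site, or None if coverage fails.

    Coverage is assessed on known abundances only, before the homogeneous
    fill of the residual cover.
    """
    if not check_coverage(table, coverage_threshold):
        logger.warning("site rejected: known cover %.2f below %.0f%% of site area",
                       _known_cover(table), 100 * coverage_threshold)
        return None
    filled = fill_unknown_abundances(table)
    out = {f"w{t}": cwm(filled, t) for t in TRAIT_COLUMNS}
    out["wNarea"] = wnarea(out["wNmass"], out["wLMA"])
    out["coverage"] = _known_cover(table)
    return out
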