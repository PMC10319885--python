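"""Readers and writers for FLUXNET-style half-hourly CSV files and pipeline tables.

The on-disk dialect follows the FLUXNET2015/LaThuile conventions: one row per
averaging interval, a ``TIMESTAMP_START`` column in ``YYYYMMDDHHMM`` local
standard time, and ``-9999`` as the missing-value sentinel.  Column naming
varies between releases, so the reader takes an explicit column map.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical FluxSeries columns (timestamp is the index)
FLUX_FIELDS = (
    "NEE", "GPP", "RECO", "LE", "H", "SWin", "SWin_pot", "Ta", "VPD",
    "P", "ustar", "WS", "PA", "T", "NEE_QC",
)

#: fields that are physically non-negative; values <= -9990 there are sentinels
NONNEGATIVE_FIELDS = frozenset({"GPP", "SWin", "SWin_pot", "VPD", "P", "ustar", "WS", "PA", "T"})

MANDATORY_FIELDS = ("NEE", "GPP", "LE", "H", "SWin", "Ta", "NEE_QC")

#: default FLUXNET2015 column map (gap-filled met drivers, night-time partitioning)
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "NEE": "NEE_VUT_REF",
    "GPP": "GPP_NT_VUT_REF",
    "RECO": "RECO_NT_VUT_REF",
    "LE": "LE_F_MDS",
    "H": "H_F_MDS",
    "SWin": "SW_IN_F",
    "SWin_pot": "SW_IN_POT",
    "Ta": "TA_F",
    "VPD": "VPD_F",
    "P": "P_F",
    "ustar": "USTAR",
    "WS": "WS_F",
    "PA": "PA_F",
    "T": "T_TEA",
    "NEE_QC": "NEE_VUT_REF_QC",
}

IGBP_CLASSES = frozenset({"CSH", "DBF", "EBF", "ENF", "GRA", "MF", "OSH", "SAV", "WET", "WSA"})


@dataclass
class DialectConfig:
    """How to interpret one CSV dialect.

    Parameters
    ----------
    column_map : mapping of FluxSeries field -> CSV column name.
    sentinel : missing-value sentinel (default -9999).
    timestamp_column : name of the start-of-interval timestamp column.
    """

    column_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_COLUMN_MAP))
    sentinel: float = -9999.0
    timestamp_column: str = "TIMESTAMP_START"


@dataclass
class SiteMeta:
    """Static site attributes used downstream of the flux record."""

    site_id: str
    igbp: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    elevation: float | None = None
    hc: float | None = None          # canopy height, m
    lai_max: float | None = None     # maximum leaf area index, m2 m-2
    years: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.igbp is not None and self.igbp not in IGBP_CLASSES:
            raise ValueError(f"unknown IGBP class {self.igbp!r}")
        if self.hc is not None and not self.hc > 0:
            raise ValueError("Hc must be positive")
        if self.lai_max is not None and not self.lai_max > 0:
            raise ValueError("LAImax must be positive")


class FluxSeries:
    """A per-site half-hourly (or hourly) flux and meteorology record.

    Thin wrapper over a :class:`pandas.DataFrame` with a strictly increasing,
    equally spaced ``DatetimeIndex`` (start of interval, local standard time)
    and the canonical columns in :data:`FLUX_FIELDS`.  Missing values are NaN;
    sentinel numbers never survive construction via :func:`read_flux_csv`.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.index, pd.DatetimeIndex):
            raise TypeError("FluxSeries requires a DatetimeIndex")
        if len(data) >= 2:
            steps = np.diff(data.index.asi8)
            if not (steps > 0).all():
                raise ValueError("timestamps must be strictly increasing")
            if len(set(steps)) != 1:
                raise ValueError("timestamps must be equally spaced")
            step_min = steps[0] / 60e9
            if step_min not in (30.0, 60.0):
                raise ValueError(f"time step must be 30 or 60 min, got {step_min}")
        for name in FLUX_FIELDS:
            if name not in data.columns:
                data = data.assign(**{name: np.nan})
        sw = data["SWin"]
        if (sw.dropna() < 0).any():
            raise ValueError("SWin must be non-negative where present")
        self.data = data[list(FLUX_FIELDS)]

    def __len__(self) -> int:
        return len(self.data)

    @property
    def step_seconds(self) -> float:
        """Averaging-interval length in seconds (1800 or 3600)."""
        if len(self.data) < 2:
            return 1800.0
        return float((self.data.index[1] - self.data.index[0]).total_seconds())

    @property
    def steps_per_day(self) -> int:
        return int(round(86400 / self.step_seconds))

    def __getattr__(self, name: str):
        if name in FLUX_FIELDS:
            return self.data[name]
        raise AttributeError(name)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index


def read_flux_csv(path: str | Path, dialect: DialectConfig | None = None) -> FluxSeries:
    """Read one FLUXNET-style CSV into a :class:`FluxSeries`.

    Sentinel values are converted to NaN (any value <= -9990 in a physically
    non-negative column is also treated as missing, since files mix ``-9999``
    and ``-9999.0``); all other numbers pass through bit-identically.  Unknown
    columns are ignored with a logged warning.
    """
    dialect = dialect or DialectConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, float_precision="round_trip")

    ts_col = dialect.timestamp_column
    if ts_col not in raw.columns:
        raise ValueError(f"missing mandatory column {ts_col!r}")
    for fld in MANDATORY_FIELDS:
        col = dialect.column_map.get(fld)
        if col is None or col not in raw.columns:
            raise ValueError(f"missing mandatory column {col or fld!r} (field {fld})")

    known = {ts_col} | {c for c in dialect.column_map.values() if c in raw.columns}
    unknown = [c for c in raw.columns if c not in known]
    if unknown:
        logger.warning("ignoring %d unknown columns: %s", len(unknown), unknown[:10])

    idx = pd.to_datetime(raw[ts_col].astype("int64").astype(str), format="%Y%m%d%H%M")
    if len(idx) >= 2 and not idx.is_monotonic_increasing:
        raise ValueError("non-monotone timestamps")

    out = {}
    for fld, col in dialect.column_map.items():
        if col not in raw.columns:
            continue
        vals = pd.to_numeric(raw[col], errors="coerce").to_numpy(dtype=float)
        mask = vals == dialect.sentinel
        if fld in NONNEGATIVE_FIELDS:
            mask |= vals <= -9990.0
        vals = np.where(mask, np.nan, vals)
        out[fld] = vals
    df = pd.DataFrame(out, index=pd.DatetimeIndex(idx, name="timestamp"))
    return FluxSeries(df)


def write_flux_csv(series: FluxSeries, path: str | Path,
                   dialect: DialectConfig | None = None) -> None:
    """Write a FluxSeries back to the CSV dialect read by :func:`read_flux_csv`.

    Missing values are written as the dialect sentinel; numeric values are
    written with full precision so read(write(x)) == x.
    """
    dialect = dialect or DialectConfig()
    out = pd.DataFrame({dialect.timestamp_column: series.index.strftime("%Y%m%d%H%M")})
    for fld in FLUX_FIELDS:
        col = dialect.column_map.get(fld, fld)
        out[col] = series.data[fld].to_numpy()
    out.to_csv(path, index=False, float_format="%.17g",
               na_rep=str(int(dialect.sentinel)) if dialect.sentinel == int(dialect.sentinel)
               else str(dialect.sentinel))


#: fixed column order of the site-level EFP/trait table
EFP_COLUMNS = (
    "site_id", "GPPsat", "RECOmax", "EF", "Gsmax", "WUEt", "PNUE", "Ta",
    "wLL", "wLMA", "wNmass", "wNarea", "wSSD", "Hc", "LAImax", "IGBP",
)


def write_efp_table(records: Sequence[Mapping], path: str | Path) -> None:
    """Write site-level EFP records as CSV with a fixed column order.

    Round-trips losslessly through :func:`read_efp_table`.
    """
    if len(records) == 0:
        raise ValueError("no records to write")
    rows = [{c: r.get(c) if isinstance(r, Mapping) else getattr(r, c, None) for c in EFP_COLUMNS}
            for r in records]
    df = pd.DataFrame(rows, columns=list(EFP_COLUMNS))
    if df["site_id"].duplicated().any():
        dupes = df.loc[df["site_id"].duplicated(), "site_id"].tolist()
        raise ValueError(f"duplicate site_id: {dupes}")
    df.to_csv(path, index=False, float_format="%.17g")


def read_efp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EFP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"EFP table missing columns {missing}")
    return df[list(EFP_COLUMNS)]


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (thresholds, inputs, versions) for provenance."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str))
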