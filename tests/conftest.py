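import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from ecospectra.flux_io import FLUX_FIELDS, FluxSeries

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


def make_series(n=48, step="30min", start="2020-06-01", **columns) -> FluxSeries:
    """Build a FluxSeries from scalars or arrays; unspecified fields are NaN.

    NEE_QC defaults to 0 (measured) so quality filtering is a no-op unless a
    test sets flags explicitly.
    """
    idx = pd.date_range(start, periods=n, freq=step, name="timestamp")
    data = {}
    for fld in FLUX_FIELDS:
        val = columns.get(fld, 0.0 if fld == "NEE_QC" else np.nan)
        data[fld] = np.broadcast_to(np.asarray(val, dtype=float), (n,)).copy()
    return FluxSeries(pd.DataFrame(data, index=idx))


@pytest.fixture
def day_series():
    """Two days of half-hourly records with a plain diurnal radiation cycle."""
    n = 96
    hour = (np.arange(n) % 48) / 2.0
    swin = np.clip(800 * np.sin(np.pi * (hour - 6) / 12), 0, None)
    return make_series(n=n, SWin=swin, SWin_pot=swin / 0.75, GPP=5.0, NEE=-3.0,
                       LE=100.0, H=100.0, Ta=15.0, VPD=1.0, P=0.0, ustar=0.3,
                       WS=2.0, PA=100.0)
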