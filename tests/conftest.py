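import numpy as np
import pandas as pd
import pytest

from echolayers.echo import Echogram, EsduRecord


def make_echogram(
    sv,
    depths=None,
    lat0=14.5,
    lon0=-17.3,
    col_spacing_nmi=0.02,
    bottom=140.0,
    start="2000-11-15 12:00:00",
):
    """Small echogram on a northward track with evenly spaced columns."""
    sv = np.asarray(sv, dtype=float)
    n_depth, n_col = sv.shape
    if depths is None:
        depths = np.arange(n_depth) + 0.5
    lats = lat0 + np.arange(n_col) * col_spacing_nmi / 60.0
    times = pd.Timestamp(start) + pd.to_timedelta(np.arange(n_col) * 10, unit="s")
    return Echogram(
        sv=sv,
        depths=np.asarray(depths, dtype=float),
        times=pd.DatetimeIndex(times),
        lats=lats,
        lons=np.full(n_col, lon0),
        bottom_depth=np.full(n_col, float(bottom)),
    )


def make_record(
    esdu_index=0,
    lat=14.5,
    lon=-17.3,
    time="2000-11-15 12:00:00",
    bottom_depth=100.0,
    nasc=None,
    diel="unset",
    area="",
    by_depth=None,
    depth_bins=None,
):
    nasc = dict(nasc or {"PG": 1.0, "PFG": 10.0, "TG": 11.0})
    if depth_bins is None:
        depth_bins = np.arange(0.0, 5.0)
    if by_depth is None:
        by_depth = {
            k: np.full(len(depth_bins), v / len(depth_bins)) for k, v in nasc.items()
        }
    return EsduRecord(
        esdu_index=esdu_index,
        lat=lat,
        lon=lon,
        time=pd.Timestamp(time),
        bottom_depth=bottom_depth,
        nasc=nasc,
        nasc_by_depth=by_depth,
        depth_bins=np.asarray(depth_bins, dtype=float),
        diel=diel,
        area=area,
    )


@pytest.fixture
def echogram_factory():
    return make_echogram


@pytest.fixture
def record_factory():
    return make_record
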