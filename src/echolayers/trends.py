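"""Climatology, anomaly and rank-based trend machinery.

Environmental series (SST, upwelling-favourable wind, surface
chlorophyll-a) arrive as monthly means per area.  Anomalies are the
deviation of each value from its calendar-month long-term average, so the
seasonal cycle is removed before any trend test.  Monotone trends are
tested with Spearman's rank correlation against observation time — the
standard distribution-free trend test for short, non-Gaussian
environmental and acoustic series — with an exact permutation p-value at
very small n and the t-approximation otherwise.  The classic 13-term
moving average (end weights 1/24, interior 1/12) is provided for display
smoothing of monthly series: it annihilates the 12-month cycle exactly
and preserves linear trends.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .echo import EsduRecord

__all__ = [
    "EnvSeries",
    "AnomalySeries",
    "TrendResult",
    "monthly_climatology",
    "anomalies",
    "smooth_13term",
    "spearman_trend",
    "acoustic_annual_series",
]

MONTH_NAMES = (
    "January February March April May June July August "
    "September October November December"
).split()


@dataclass
class EnvSeries:
    """A monthly environmental series for one variable in one area."""

    variable: str  # SST (degC), UW (m s-1), SSC (mg m-3)
    times: pd.DatetimeIndex
    values: np.ndarray
    area: str = ""

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values length mismatch")
        if len(self.times) > 1:
            gaps = self.times.to_period("M").astype("int64")
            if np.any(np.diff(gaps) != 1):
                raise ValueError("times must be consecutive calendar months")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "area": self.area,
                "year": self.times.year,
                "month": self.times.month,
                "value": self.values,
            }
        )


@dataclass
class AnomalySeries:
    """Deviations of a series from its monthly climatology."""

    variable: str
    times: pd.DatetimeIndex
    values: np.ndarray
    baseline: np.ndarray  # the 12 climatology values used
    area: str = ""


@dataclass
class TrendResult:
    """Spearman rank-correlation trend test result."""

    rho: float
    p_value: float
    n: int
    degenerate: bool = False


# ---------------------------------------------------------------------------


def monthly_climatology(series: EnvSeries) -> np.ndarray:
    """Long-term mean per calendar month (12 values, January first).

    Missing values are excluded from their month's mean; a calendar month
    with no data in any year is an error because anomalies for that month
    would be undefined.
    """
    if len(series.times) < 24:
        raise ValueError("climatology needs at least 2 years of monthly data")
    frame = pd.DataFrame({"month": series.times.month, "value": series.values})
    clim = frame.groupby("month")["value"].mean()
    out = np.full(12, np.nan)
    for m in range(1, 13):
        if m in clim.index and np.isfinite(clim.loc[m]):
            out[m - 1] = clim.loc[m]
        else:
            raise ValueError(f"no data for calendar month {MONTH_NAMES[m - 1]}")
    return out


def anomalies(series: EnvSeries, climatology: np.ndarray) -> AnomalySeries:
    """Subtract each value's calendar-month climatology; NaN propagates."""
    climatology = np.asarray(climatology, dtype=float)
    if climatology.shape != (12,) or not np.all(np.isfinite(climatology)):
        raise ValueError("climatology must be 12 finite monthly values")
    anom = series.values - climatology[series.times.month - 1]
    return AnomalySeries(
        variable=series.variable,
        times=series.times,
        values=anom,
        baseline=climatology.copy(),
        area=series.area,
    )


_W13 = np.array([1 / 24] + [1 / 12] * 11 + [1 / 24])


def smooth_13term(values: Sequence[float]) -> np.ndarray:
    """Centered 13-term annual smoother for monthly data.

    Weights 1/24 at the two extreme lags and 1/12 in between, i.e. the
    average of two adjacent 12-month means.  The first and last six
    points, where the window is incomplete, are returned as NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 13:
        raise ValueError("13-term smoothing needs at least 13 points")
    out = np.full(x.size, np.nan)
    out[6:-6] = np.convolve(x, _W13[::-1], mode="valid")
    return out


# ---------------------------------------------------------------------------
# Spearman trend test


def _rho_of_ranks(rv: np.ndarray, rt: np.ndarray) -> float:
    rv = rv - rv.mean()
    rt = rt - rt.mean()
    denom = math.sqrt(float((rv**2).sum()) * float((rt**2).sum()))
    return float((rv * rt).sum() / denom)


def _exact_perm_p(rv: np.ndarray, rt: np.ndarray, rho_obs: float) -> float:
    """Two-sided p by full enumeration over permutations of the value ranks."""
    n = rv.size
    perms = np.array(list(itertools.permutations(rv)))
    rvc = perms - perms.mean(axis=1, keepdims=True)
    rtc = rt - rt.mean()
    denom = np.sqrt((rvc**2).sum(axis=1) * (rtc**2).sum())
    rhos = (rvc * rtc).sum(axis=1) / denom
    hits = int(np.sum(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return hits / math.factorial(n)


def spearman_trend(values: Sequence[float], times: Sequence[float]) -> TrendResult:
    """Spearman rank-correlation test of values against observation time.

    rho is the product-moment correlation of mid-ranks of the values with
    the ranks of the times.  Missing values are dropped pairwise.  The
    two-sided p-value comes from exact permutation enumeration for
    n <= 9 and from the t-approximation above.  A constant series has no
    defined rank correlation and is reported as rho = 0, p = 1 with the
    degenerate flag set.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if v.shape != t.shape:
        raise ValueError("values and times length mismatch")
    keep = np.isfinite(v) & np.isfinite(t)
    v, t = v[keep], t[keep]
    n = v.size
    if n < 4:
        raise ValueError("spearman_trend needs at least 4 points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.all(v == v[0]):
        return TrendResult(rho=0.0, p_value=1.0, n=n, degenerate=True)

    rv = stats.rankdata(v)  # mid-ranks for ties
    rt = stats.rankdata(t)
    rho = _rho_of_ranks(rv, rt)
    if n <= 9:
        p = _exact_perm_p(rv, rt, rho)
    else:
        tt = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = 2.0 * stats.t.sf(abs(tt), df=n - 2)
    return TrendResult(rho=rho, p_value=min(1.0, float(p)), n=n)


# ---------------------------------------------------------------------------
# acoustic annual series


def acoustic_annual_series(
    records: Iterable[EsduRecord], group: str, area: str = ""
) -> pd.DataFrame:
    """Annual mean NASC per echo class with anomalies vs the all-year mean.

    Surveys run once per year in the same season, so the monthly
    climatology degenerates to a single long-term mean and the annual
    anomaly is simply the yearly mean minus the grand mean of yearly
    means.  Returns a frame with columns year, mean_nasc, anomaly.
    """
    recs = [r for r in records if not area or r.area == area]
    if not recs:
        raise ValueError(f"no records in stratum (group={group}, area={area!r})")
    frame = pd.DataFrame(
        {"year": [r.year for r in recs], "nasc": [r.nasc[group] for r in recs]}
    )
    yearly = frame.groupby("year")["nasc"].mean().rename("mean_nasc").reset_index()
    if yearly["year"].nunique() < 2:
        raise ValueError("acoustic series needs at least 2 survey years")
    yearly["anomaly"] = yearly["mean_nasc"] - yearly["mean_nasc"].mean()
    return yearly
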