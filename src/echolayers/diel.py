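"""Diel labelling and diel-vertical-migration (DVM) statistics.

Day and night are separated by the geometric solar altitude: an ESDU is
*day* when the sun stands above +18 deg, *night* below -18 deg, and
*transition* inside the astronomical-twilight band in between.  Transition
ESDUs are removed before any day/night contrast so migrating layers caught
mid-ascent do not bias the profiles.

The migration signal itself is summarised per 1-m depth bin as

    delta_DVM(z) = mean night NASC(z) - mean day NASC(z),

positive near the surface for normal DVM (shallow at night), negative at
the daytime residence depth.  Day/night differences in the profile are
tested with the Wilcoxon test (paired signed-rank by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .echo import EsduRecord

__all__ = [
    "DvmProfile",
    "solar_altitude",
    "label_diel",
    "drop_transitions",
    "dvm_profile",
    "wilcoxon_daynight",
]

log = logging.getLogger(__name__)

DIEL_THRESHOLD_DEG = 18.0


# ---------------------------------------------------------------------------
# solar position (NOAA general solar-position equations)


def solar_altitude(lat, lon, time):
    """Geometric solar elevation angle in degrees, in [-90, 90].

    Implements the NOAA general solar-position equations (Julian-century
    polynomial ephemeris for the sun's apparent longitude, obliquity and
    the equation of time).  No atmospheric refraction is applied: at the
    +-18 deg twilight thresholds used for diel labelling, refraction
    (~0.1 deg near the horizon, less at depression angles) is negligible
    against the width of the band.

    Accepts scalars or arrays; broadcasting follows numpy rules.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("latitude must be in [-90, 90] and longitude in [-180, 180]")
    times = pd.DatetimeIndex(np.atleast_1d(np.asarray(time, dtype="datetime64[ns]")))
    if times.isna().any():
        raise ValueError("invalid timestamp")
    jd = times.to_julian_date().to_numpy()
    scalar = np.isscalar(time) or (getattr(time, "ndim", 0) == 0 and len(times) == 1)

    jc = (jd - 2451545.0) / 36525.0
    rad = np.radians

    l0 = np.mod(280.46646 + jc * (36000.76983 + 0.0003032 * jc), 360.0)
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    c = (
        np.sin(rad(m)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(rad(2 * m)) * (0.019993 - 0.000101 * jc)
        + np.sin(rad(3 * m)) * 0.000289
    )
    true_long = l0 + c
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * np.sin(rad(omega))

    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(rad(omega))

    decl = np.degrees(np.arcsin(np.sin(rad(eps)) * np.sin(rad(app_long))))

    y = np.tan(rad(eps) / 2.0) ** 2
    eqtime = 4.0 * np.degrees(
        y * np.sin(2 * rad(l0))
        - 2.0 * ecc * np.sin(rad(m))
        + 4.0 * ecc * y * np.sin(rad(m)) * np.cos(2 * rad(l0))
        - 0.5 * y**2 * np.sin(4 * rad(l0))
        - 1.25 * ecc**2 * np.sin(2 * rad(m))
    )

    minutes_utc = (
        times.hour * 60.0
        + times.minute
        + times.second / 60.0
        + times.microsecond / 6.0e7
    ).to_numpy()
    tst = np.mod(minutes_utc + eqtime + 4.0 * lon, 1440.0)
    ha = tst / 4.0 - 180.0

    sin_alt = np.sin(rad(lat)) * np.sin(rad(decl)) + np.cos(rad(lat)) * np.cos(
        rad(decl)
    ) * np.cos(rad(ha))
    alt = np.degrees(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))
    return float(alt[0]) if scalar and alt.size == 1 else alt


# ---------------------------------------------------------------------------
# diel labelling


def label_diel(
    records: Iterable[EsduRecord], threshold_deg: float = DIEL_THRESHOLD_DEG
) -> list[EsduRecord]:
    """Set each record's diel field from the sun's altitude at its position.

    altitude > +threshold -> day; < -threshold -> night; else transition.
    """
    records = list(records)
    if not records:
        return records
    alt = solar_altitude(
        np.array([r.lat for r in records]),
        np.array([r.lon for r in records]),
        np.array([np.datetime64(pd.Timestamp(r.time)) for r in records]),
    )
    alt = np.atleast_1d(alt)
    for r, a in zip(records, alt):
        if a > threshold_deg:
            r.diel = "day"
        elif a < -threshold_deg:
            r.diel = "night"
        else:
            r.diel = "transition"
    return records


def drop_transitions(records: Iterable[EsduRecord]) -> list[EsduRecord]:
    """Remove twilight ESDUs; idempotent."""
    records = list(records)
    kept = [r for r in records if r.diel in ("day", "night")]
    n_dropped = len(records) - len(kept)
    log.info("dropped %d transition ESDUs of %d", n_dropped, len(records))
    if records and not kept:
        warnings.warn("all records fall in the diel transition band", stacklevel=2)
    return kept


# ---------------------------------------------------------------------------
# DVM profiles


@dataclass
class DvmProfile:
    """Mean day/night NASC per 1-m depth bin for one echo class."""

    group: str
    area: str
    depth_bins: np.ndarray
    mean_day: np.ndarray
    mean_night: np.ndarray
    delta_dvm: np.ndarray
    n_day: int
    n_night: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "area": self.area,
                "depth_bin": self.depth_bins,
                "mean_day": self.mean_day,
                "mean_night": self.mean_night,
                "delta_dvm": self.delta_dvm,
                "n_day": self.n_day,
                "n_night": self.n_night,
            }
        )


def dvm_profile(
    records: Sequence[EsduRecord],
    group: str,
    area: str = "",
    log_transform: bool = False,
    log_offset: float = 1.0,
) -> DvmProfile:
    """Build the day-vs-night mean vertical profile for one echo class.

    Per 1-m depth bin, ``mean_day`` and ``mean_night`` average the
    per-ESDU NASC over the day and night strata; with ``log_transform``
    the ESDU values are log10(x + offset)-transformed *before* averaging
    (zero-NASC bins stay finite).  ``delta_dvm`` is always night minus day
    of the untransformed means, in m^2 nmi^-2.
    """
    recs = [r for r in records if not area or r.area == area]
    day = [r for r in recs if r.diel == "day"]
    night = [r for r in recs if r.diel == "night"]
    if not day or not night:
        missing = "day" if not day else "night"
        raise ValueError(f"no {missing} records in stratum (group={group}, area={area!r})")

    bins = day[0].depth_bins
    for r in day + night:
        if not np.array_equal(r.depth_bins, bins):
            raise ValueError("records carry inconsistent depth bins")

    def stack(rs: list[EsduRecord]) -> np.ndarray:
        return np.stack([r.nasc_by_depth[group] for r in rs])

    raw_day, raw_night = stack(day), stack(night)
    mean_day_raw = raw_day.mean(axis=0)
    mean_night_raw = raw_night.mean(axis=0)
    if log_transform:
        mean_day = np.log10(raw_day + log_offset).mean(axis=0)
        mean_night = np.log10(raw_night + log_offset).mean(axis=0)
    else:
        mean_day, mean_night = mean_day_raw, mean_night_raw

    return DvmProfile(
        group=group,
        area=area,
        depth_bins=bins.copy(),
        mean_day=mean_day,
        mean_night=mean_night,
        delta_dvm=mean_night_raw - mean_day_raw,
        n_day=len(day),
        n_night=len(night),
    )


# ---------------------------------------------------------------------------
# Wilcoxon day-night test


def wilcoxon_daynight(
    day_values: Sequence[float],
    night_values: Sequence[float],
    paired: bool = True,
) -> tuple[float, float]:
    """Test for a day/night difference with the Wilcoxon test.

    Paired mode (default) runs the signed-rank test on night - day
    differences: zero differences are dropped, ties among the absolute
    differences get mid-ranks, and the reported statistic W is the rank
    sum of the less-frequent difference sign.  The p-value is exact for
    n <= 25 tie-free pairs and a normal approximation otherwise.  Unpaired
    mode runs the rank-sum (Mann-Whitney) equivalent.

    Returns (statistic, two-sided p-value).
    """
    day = np.asarray(day_values, dtype=float)
    night = np.asarray(night_values, dtype=float)
    if paired:
        if day.shape != night.shape:
            raise ValueError("paired mode needs equal-length day and night lists")
        d = night - day
        d = d[d != 0.0]
        if d.size == 0:
            warnings.warn("all day-night differences are zero", stacklevel=2)
            return 0.0, 1.0
        if d.size < 3:
            raise ValueError("paired Wilcoxon needs at least 3 non-zero pairs")
        ranks = stats.rankdata(np.abs(d))
        r_pos = float(ranks[d > 0].sum())
        r_neg = float(ranks[d < 0].sum())
        n_pos, n_neg = int((d > 0).sum()), int((d < 0).sum())
        if n_pos < n_neg:
            w = r_pos
        elif n_neg < n_pos:
            w = r_neg
        else:
            w = min(r_pos, r_neg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(
                night, day, zero_method="wilcox", alternative="two-sided"
            )
        return w, float(res.pvalue)
    if day.size < 3 or night.size < 3:
        raise ValueError("unpaired Wilcoxon needs at least 3 values per stratum")
    res = stats.mannwhitneyu(night, day, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
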