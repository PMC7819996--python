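"""Independent brute-force oracles, written separately from the library code.

Everything here favours obvious correctness over speed: explicit loops,
full enumeration, Fractions for exact p-values.  These implementations are
the reference the fast library paths are checked against.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# echo-integration: triple loop over (esdu, column, cell)


def brute_force_nasc(
    sv: np.ndarray,
    depths: np.ndarray,
    bottom_depth: np.ndarray,
    col_esdu: np.ndarray,
    sv_low: float,
    sv_high: float,
    surface_offset: float,
    dz: float,
) -> dict[int, float]:
    """Per-ESDU NASC for one Sv band, cell by cell."""
    coeff = 4.0 * math.pi * 1852.0**2
    out: dict[int, float] = {}
    for e in sorted(set(int(x) for x in col_esdu)):
        cols = [j for j in range(sv.shape[1]) if col_esdu[j] == e]
        col_vals = []
        for j in cols:
            acc = 0.0
            for i in range(sv.shape[0]):
                if depths[i] < surface_offset:
                    continue
                if depths[i] > bottom_depth[j]:
                    continue
                v = sv[i, j]
                if not np.isfinite(v):
                    continue
                if sv_low <= v < sv_high:
                    acc += 10.0 ** (v / 10.0) * dz
            col_vals.append(coeff * acc)
        out[e] = sum(col_vals) / len(col_vals)
    return out


# ---------------------------------------------------------------------------
# weighted barycenter: plain accumulation


def brute_force_barycenter(lats, lons, weights) -> tuple[float, float]:
    sw = sx = sy = 0.0
    for la, lo, w in zip(lats, lons, weights):
        sw += w
        sx += w * la
        sy += w * lo
    return sx / sw, sy / sw


# ---------------------------------------------------------------------------
# Spearman: rank correlation + exact permutation p by full enumeration


def _ranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    return ranks


def _pearson(x, y) -> float:
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def brute_force_spearman(values, times) -> tuple[float, Fraction]:
    """(rho, exact two-sided permutation p) by enumerating all n! orders."""
    rv, rt = _ranks(list(values)), _ranks(list(times))
    rho = _pearson(rv, rt)
    n = len(rv)
    hits = 0
    total = 0
    for perm in itertools.permutations(rv):
        total += 1
        if abs(_pearson(list(perm), rt)) >= abs(rho) - 1e-12:
            hits += 1
    return rho, Fraction(hits, total)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank: exact p by enumerating all 2^n sign assignments


def brute_force_wilcoxon_paired(day, night) -> tuple[float, Fraction]:
    """(W, exact two-sided p) for tie-free non-zero differences."""
    d = [b - a for a, b in zip(day, night) if b != a]
    n = len(d)
    absd = [abs(x) for x in d]
    assert len(set(absd)) == n, "oracle requires tie-free |differences|"
    ranks = _ranks(absd)
    r_pos = sum(r for r, x in zip(ranks, d) if x > 0)
    r_neg = sum(r for r, x in zip(ranks, d) if x < 0)
    n_pos = sum(1 for x in d if x > 0)
    n_neg = n - n_pos
    if n_pos < n_neg:
        w = r_pos
    elif n_neg < n_pos:
        w = r_neg
    else:
        w = min(r_pos, r_neg)
    w_min = min(r_pos, r_neg)
    # null: each sign equally likely; two-sided p on min rank sum
    hits = 0
    for signs in itertools.product((1, -1), repeat=n):
        rp = sum(r for r, s in zip(ranks, signs) if s > 0)
        rn = sum(r for r, s in zip(ranks, signs) if s < 0)
        if min(rp, rn) <= w_min + 1e-12:
            hits += 1
    return w, Fraction(hits, 2**n)


# ---------------------------------------------------------------------------
# solar position: Michalsky (1988) Astronomical Almanac algorithm


def michalsky_solar_altitude(lat: float, lon: float, time) -> float:
    """Geometric solar elevation, low-precision almanac formulation."""
    t = pd.Timestamp(time)
    jd = t.to_julian_date()
    n = jd - 2451545.0
    mnlong = (280.460 + 0.9856474 * n) % 360.0
    mnanom = math.radians((357.528 + 0.9856003 * n) % 360.0)
    eclong = math.radians(
        (mnlong + 1.915 * math.sin(mnanom) + 0.020 * math.sin(2 * mnanom)) % 360.0
    )
    oblqec = math.radians(23.439 - 0.0000004 * n)
    num = math.cos(oblqec) * math.sin(eclong)
    den = math.cos(eclong)
    ra = math.atan2(num, den)  # radians
    dec = math.asin(math.sin(oblqec) * math.sin(eclong))
    hour = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    # gmst from whole days since the epoch at 0h UT, plus the UT hour
    n0 = math.floor(jd - 0.5) + 0.5 - 2451545.0
    gmst = (6.697375 + 0.0657098242 * n0 + 1.00273790935 * hour) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = math.radians(lmst * 15.0) - ra
    sin_alt = math.sin(dec) * math.sin(math.radians(lat)) + math.cos(dec) * math.cos(
        math.radians(lat)
    ) * math.cos(ha)
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_alt))))


# ---------------------------------------------------------------------------
# weighted centroid of a vertical profile (layer-depth recovery)


def profile_centroid(depths, sv_db) -> float:
    """Linear-sv weighted mean depth of one column, ignoring the noise floor."""
    w = [10.0 ** (v / 10.0) for v in sv_db]
    floor = min(w)
    w = [x - floor for x in w]
    total = sum(w)
    return sum(d * x for d, x in zip(depths, w)) / total
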