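"""North/South area split and biomass-weighted barycenters.

The survey region is cut at Cap Blanc (20.77 deg N), the faunistic limit
between the two upwelling regimes; the boundary latitude itself belongs to
the northern area.  The annual centre of gravity of a trophic group is the
NASC-weighted mean position of its ESDUs,

    lat_a = sum_i w_i * lat_i / sum_i w_i   (and likewise for longitude),

with w_i the ESDU's linear-domain NASC for the group in year a.  Planar
weighted means of raw degrees are adequate here: the region spans ~19 deg
of latitude close to the prime meridian, where curvature corrections to a
within-area centroid are far below the interannual jitter of interest.
Interannual displacement of the barycenter is tested per coordinate with
the Spearman trend test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .echo import EsduRecord
from .trends import TrendResult, spearman_trend

__all__ = [
    "CAP_BLANC_LAT",
    "Barycenter",
    "split_area",
    "barycenter",
    "barycenter_trend",
]

CAP_BLANC_LAT = 20.77


@dataclass
class Barycenter:
    """Biomass-weighted mean position of one group in one area-year."""

    year: int
    area: str
    group: str
    lat: float
    lon: float
    total_weight: float


def split_area(
    records: Iterable[EsduRecord], boundary_lat: float = CAP_BLANC_LAT
) -> list[EsduRecord]:
    """Tag every record north (lat >= boundary) or south (lat < boundary)."""
    records = list(records)
    for r in records:
        r.area = "north" if r.lat >= boundary_lat else "south"
    return records


def barycenter(
    records: Iterable[EsduRecord], year: int, area: str, group: str
) -> Barycenter:
    """NASC-weighted mean position of a group in one year-area stratum."""
    recs = [r for r in records if r.year == year and r.area == area]
    if not recs:
        raise ValueError(f"no records for year={year}, area={area!r}")
    w = np.array([r.nasc[group] for r in recs], dtype=float)
    if np.any(w < 0):
        raise ValueError("negative NASC weight")
    total = float(w.sum())
    if total <= 0.0:
        raise ValueError(f"no biomass in stratum (year={year}, area={area!r}, group={group})")
    lats = np.array([r.lat for r in recs])
    lons = np.array([r.lon for r in recs])
    return Barycenter(
        year=year,
        area=area,
        group=group,
        lat=float((w * lats).sum() / total),
        lon=float((w * lons).sum() / total),
        total_weight=total,
    )


def barycenter_trend(
    barycenters: Sequence[Barycenter],
) -> dict[str, TrendResult]:
    """Spearman trend of the yearly barycenter, per coordinate.

    Returns {"lat": TrendResult, "lon": TrendResult}; needs at least 4
    yearly positions for the rank test to carry any information.
    """
    bcs = sorted(barycenters, key=lambda b: b.year)
    years = [b.year for b in bcs]
    if len(set(years)) != len(years):
        raise ValueError("duplicate years in barycenter series")
    if len(bcs) < 4:
        raise ValueError("barycenter trend needs at least 4 yearly positions")
    t = np.array(years, dtype=float)
    return {
        "lat": spearman_trend([b.lat for b in bcs], t),
        "lon": spearman_trend([b.lon for b in bcs], t),
    }


def barycenters_to_frame(barycenters: Iterable[Barycenter]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "year": b.year,
                "area": b.area,
                "group": b.group,
                "lat": b.lat,
                "lon": b.lon,
                "total_weight": b.total_weight,
            }
            for b in barycenters
        ]
    )
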