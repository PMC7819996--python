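"""Echo-integration of volume-backscatter grids into per-ESDU NASC.

The relative abundance proxy used throughout the package is the Nautical
Area Scattering Coefficient (NASC, or ``s_A``, in m^2 nmi^-2),

    NASC = 4 * pi * 1852**2 * sum_z sv(z) * dz,

where ``sv = 10**(Sv/10)`` is the linear volume backscattering coefficient
(m^-1) and the sum runs over depth bins retained after the surface offset
and seabed exclusion.  Backscatter is split into trophic echo classes by
half-open Sv bands before integration: the plankton group PG [-80, -65) dB,
the pelagic fish group PFG [-65, -20) dB, and the total group TG [-80, -20)
dB.  Along-track integration cells (ESDUs, elementary sampling distance
units) are 0.1 nmi by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "Echogram",
    "EchoClass",
    "EsduRecord",
    "DEFAULT_CLASSES",
    "classify_sv",
    "integrate_esdu",
    "shelf_filter",
    "records_to_frame",
    "records_by_depth_frame",
]

log = logging.getLogger(__name__)

NMI_M = 1852.0
#: 4*pi*1852^2 — converts an integrated linear sv column (m^-1 * m) to m^2 nmi^-2.
NASC_COEFF = 4.0 * math.pi * NMI_M**2


# ---------------------------------------------------------------------------
# containers


@dataclass
class Echogram:
    """A depth x along-track grid of volume backscattering strength.

    Attributes
    ----------
    sv : (n_depth, n_col) float array, dB re 1 m^-1.  NaN marks missing.
    depths : bin-centre depths in metres, strictly ascending.
    times : UTC timestamp per column.
    lats, lons : position per column, degrees.
    bottom_depth : seabed depth per column, metres.
    """

    sv: np.ndarray
    depths: np.ndarray
    times: pd.DatetimeIndex
    lats: np.ndarray
    lons: np.ndarray
    bottom_depth: np.ndarray

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        self.times = pd.DatetimeIndex(self.times)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.bottom_depth = np.asarray(self.bottom_depth, dtype=float)
        n_depth, n_col = self.sv.shape
        if self.depths.shape != (n_depth,):
            raise ValueError("depths length does not match sv rows")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly ascending")
        for name, arr in (
            ("times", self.times),
            ("lats", self.lats),
            ("lons", self.lons),
            ("bottom_depth", self.bottom_depth),
        ):
            if len(arr) != n_col:
                raise ValueError(f"{name} length does not match sv columns")

    @property
    def n_columns(self) -> int:
        return self.sv.shape[1]

    # -- gridded I/O (named dims: depth, column) ----------------------------

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"Sv": (("depth", "column"), self.sv)},
            coords={
                "depth": ("depth", self.depths),
                "column": ("column", np.arange(self.n_columns)),
                "time": ("column", self.times),
                "lat": ("column", self.lats),
                "lon": ("column", self.lons),
                "bottom_depth": ("column", self.bottom_depth),
            },
            attrs={"Sv_units": "dB re 1 m-1", "depth_units": "m"},
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "Echogram":
        return cls(
            sv=ds["Sv"].values,
            depths=ds["depth"].values,
            times=pd.DatetimeIndex(ds["time"].values),
            lats=ds["lat"].values,
            lons=ds["lon"].values,
            bottom_depth=ds["bottom_depth"].values,
        )

    def to_netcdf(self, path: str | Path) -> None:
        # NetCDF3 via the scipy engine; datetimes stored as CF-encoded floats.
        self.to_dataset().to_netcdf(
            path,
            engine="scipy",
            encoding={
                "time": {"units": "seconds since 1970-01-01", "dtype": "float64"}
            },
        )

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "Echogram":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())

    # -- plain-CSV fallback: one long cell table plus a per-column track ----

    def to_csv(self, cells_path: str | Path, track_path: str | Path) -> None:
        n_depth, n_col = self.sv.shape
        cells = pd.DataFrame(
            {
                "column": np.repeat(np.arange(n_col), n_depth),
                "depth": np.tile(self.depths, n_col),
                "Sv": self.sv.T.ravel(),
            }
        )
        cells.to_csv(cells_path, index=False, float_format="%.17g")
        track = pd.DataFrame(
            {
                "column": np.arange(n_col),
                "time": self.times.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                "lat": self.lats,
                "lon": self.lons,
                "bottom_depth": self.bottom_depth,
            }
        )
        track.to_csv(track_path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, cells_path: str | Path, track_path: str | Path) -> "Echogram":
        cells = pd.read_csv(cells_path, float_precision="round_trip")
        track = pd.read_csv(track_path, float_precision="round_trip")
        depths = np.sort(cells["depth"].unique())
        n_col = int(cells["column"].max()) + 1
        sv = (
            cells.pivot(index="depth", columns="column", values="Sv")
            .reindex(index=depths, columns=np.arange(n_col))
            .to_numpy()
        )
        return cls(
            sv=sv,
            depths=depths,
            times=pd.DatetimeIndex(pd.to_datetime(track["time"])),
            lats=track["lat"].to_numpy(),
            lons=track["lon"].to_numpy(),
            bottom_depth=track["bottom_depth"].to_numpy(),
        )


@dataclass(frozen=True)
class EchoClass:
    """Half-open Sv band [sv_low, sv_high) assigned to a trophic group."""

    name: str
    sv_low: float
    sv_high: float

    def __post_init__(self) -> None:
        if not self.sv_low < self.sv_high:
            raise ValueError(f"EchoClass {self.name}: sv_low must be < sv_high")

    def contains(self, sv_db: float | np.ndarray) -> bool | np.ndarray:
        return (sv_db >= self.sv_low) & (sv_db < self.sv_high)


DEFAULT_CLASSES: tuple[EchoClass, ...] = (
    EchoClass("PG", -80.0, -65.0),
    EchoClass("PFG", -65.0, -20.0),
    EchoClass("TG", -80.0, -20.0),
)


@dataclass
class EsduRecord:
    """One elementary sampling distance unit of the integrated survey track."""

    esdu_index: int
    lat: float
    lon: float
    time: pd.Timestamp
    bottom_depth: float
    nasc: dict[str, float]
    nasc_by_depth: dict[str, np.ndarray]
    depth_bins: np.ndarray
    diel: str = "unset"
    area: str = ""
    n_cells: int = 0
    n_missing: int = 0
    flagged: bool = False

    @property
    def year(self) -> int:
        return int(pd.Timestamp(self.time).year)


# ---------------------------------------------------------------------------
# operations


def _check_classes(classes: Sequence[EchoClass]) -> None:
    """Non-total classes must not overlap (TG deliberately spans the others)."""
    partition = [c for c in classes if c.name != "TG"]
    for i, a in enumerate(partition):
        for b in partition[i + 1 :]:
            if a.sv_low < b.sv_high and b.sv_low < a.sv_high:
                raise ValueError(
                    f"echo classes {a.name} and {b.name} overlap: "
                    f"[{a.sv_low},{a.sv_high}) vs [{b.sv_low},{b.sv_high})"
                )


def classify_sv(
    sv_value: float, classes: Sequence[EchoClass] = DEFAULT_CLASSES
) -> str:
    """Assign a single Sv value (dB) to the narrowest containing echo class.

    Values outside every band (below the all-trophic floor or at/above the
    fish-band ceiling) return ``"excluded"``.  Membership is by half-open
    interval, so -65 dB belongs to PFG, not PG.
    """
    _check_classes(classes)
    hits = [c for c in classes if c.contains(sv_value)]
    if not hits:
        return "excluded"
    # narrowest band wins so TG never shadows PG/PFG
    return min(hits, key=lambda c: c.sv_high - c.sv_low).name


def _haversine_nmi(
    lat1: np.ndarray, lon1: np.ndarray, lat2: np.ndarray, lon2: np.ndarray
) -> np.ndarray:
    """Great-circle distance between successive fixes, in nautical miles."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    # earth radius 6371 km in nmi
    return 2.0 * 6371000.0 / NMI_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _depth_bin_edges(depths: np.ndarray) -> np.ndarray:
    """1-m output bins spanning the grid; bin b covers [b, b+1)."""
    lo = math.floor(depths.min())
    hi = math.ceil(depths.max()) + 1
    return np.arange(lo, hi, 1.0)


def integrate_esdu(
    echogram: Echogram,
    esdu_length_nmi: float = 0.1,
    surface_offset_m: float = 10.0,
    classes: Sequence[EchoClass] = DEFAULT_CLASSES,
) -> list[EsduRecord]:
    """Echo-integrate an Sv grid into per-ESDU, per-class NASC.

    Columns are grouped into along-track cells of ``esdu_length_nmi``
    (cumulative great-circle distance).  Within an ESDU the per-column
    depth integrals are averaged, so NASC is an areal density independent
    of ping rate.  Cells shallower than ``surface_offset_m`` (bin centre)
    or below the column's bottom depth are excluded; cells whose Sv falls
    outside a class band contribute zero to that class.  Missing (NaN)
    cells contribute zero and are counted; an ESDU with more than half of
    its water-column cells missing is flagged.

    A trailing partial ESDU is kept when it covers at least half the
    nominal length.
    """
    if esdu_length_nmi <= 0:
        raise ValueError("esdu_length_nmi must be positive")
    _check_classes(classes)

    depths = echogram.depths
    if depths.max() < surface_offset_m:
        raise ValueError("echogram does not reach below the surface offset")
    dz = float(np.median(np.diff(depths))) if len(depths) > 1 else 1.0

    # cumulative along-track distance; column i sits at dist[i]
    d_step = _haversine_nmi(
        echogram.lats[:-1], echogram.lons[:-1], echogram.lats[1:], echogram.lons[1:]
    )
    dist = np.concatenate([[0.0], np.cumsum(d_step)])
    esdu_of_col = np.floor(dist / esdu_length_nmi).astype(int)

    sv_lin = 10.0 ** (echogram.sv / 10.0)
    missing = ~np.isfinite(echogram.sv)
    sv_db = np.where(missing, -np.inf, echogram.sv)
    sv_lin = np.where(missing, 0.0, sv_lin)

    # validity mask: below the surface offset, above the seabed
    valid = (depths[:, None] >= surface_offset_m) & (
        depths[:, None] <= echogram.bottom_depth[None, :]
    )

    edges = _depth_bin_edges(depths)
    bin_index = np.clip(
        np.searchsorted(edges, depths, side="right") - 1, 0, len(edges) - 1
    )

    # per-column, per-class integrated sv (m^-1 * m) and per-1-m-bin pieces
    col_int: dict[str, np.ndarray] = {}
    col_by_depth: dict[str, np.ndarray] = {}
    for c in classes:
        in_band = c.contains(sv_db) & valid
        contrib = np.where(in_band, sv_lin, 0.0) * dz
        col_int[c.name] = NASC_COEFF * contrib.sum(axis=0)
        by_depth = np.zeros((len(edges), echogram.n_columns))
        np.add.at(by_depth, bin_index, contrib)
        col_by_depth[c.name] = NASC_COEFF * by_depth

    total_dist = dist[-1]
    records: list[EsduRecord] = []
    for e in np.unique(esdu_of_col):
        cols = np.flatnonzero(esdu_of_col == e)
        start = e * esdu_length_nmi
        covered = min(total_dist, start + esdu_length_nmi) - start
        if e == esdu_of_col.max() and e > 0 and covered < 0.5 * esdu_length_nmi:
            log.info("dropping trailing partial ESDU %d (%.3f nmi)", e, covered)
            continue
        mid = cols[len(cols) // 2]
        n_valid = int(valid[:, cols].sum())
        n_miss = int((missing[:, cols] & valid[:, cols]).sum())
        rec = EsduRecord(
            esdu_index=int(e),
            lat=float(echogram.lats[mid]),
            lon=float(echogram.lons[mid]),
            time=pd.Timestamp(echogram.times[mid]),
            bottom_depth=float(echogram.bottom_depth[mid]),
            nasc={c.name: float(col_int[c.name][cols].mean()) for c in classes},
            nasc_by_depth={
                c.name: col_by_depth[c.name][:, cols].mean(axis=1) for c in classes
            },
            depth_bins=edges.copy(),
            n_cells=n_valid,
            n_missing=n_miss,
            flagged=n_valid > 0 and n_miss > 0.5 * n_valid,
        )
        records.append(rec)
    return records


def shelf_filter(
    records: Iterable[EsduRecord],
    min_depth_m: float = 10.0,
    max_depth_m: float = 150.0,
) -> list[EsduRecord]:
    """Keep ESDUs whose bottom depth lies on the continental shelf.

    The interval is closed: 10 m and 150 m bottoms are both retained.
    """
    records = list(records)
    kept = [r for r in records if min_depth_m <= r.bottom_depth <= max_depth_m]
    log.info("shelf filter: kept %d of %d ESDUs", len(kept), len(records))
    if not kept:
        log.warning("shelf filter removed every record")
    return kept


# ---------------------------------------------------------------------------
# tabular export


def records_to_frame(records: Iterable[EsduRecord]) -> pd.DataFrame:
    rows = [
        {
            "esdu_index": r.esdu_index,
            "time": pd.Timestamp(r.time).isoformat(),
            "lat": r.lat,
            "lon": r.lon,
            "bottom_depth": r.bottom_depth,
            "diel": r.diel,
            "area": r.area,
            **{f"NASC_{k}": v for k, v in r.nasc.items()},
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def records_by_depth_frame(records: Iterable[EsduRecord]) -> pd.DataFrame:
    """Long-format per-depth-bin NASC (esdu_index, depth_bin, class, NASC)."""
    parts = []
    for r in records:
        for cname, prof in r.nasc_by_depth.items():
            parts.append(
                pd.DataFrame(
                    {
                        "esdu_index": r.esdu_index,
                        "depth_bin": r.depth_bins,
                        "class": cname,
                        "NASC": prof,
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=["esdu_index", "depth_bin", "class", "NASC"])
    return pd.concat(parts, ignore_index=True)
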