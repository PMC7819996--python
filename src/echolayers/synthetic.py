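"""Synthetic echograms and environmental series with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, at the Sv-band level (no target-strength or sonar-equation
physics):

* sound-scattering layers that sit in their trophic Sv band — plankton in
  [-80, -65) dB, fish in [-65, -20) dB — with Gaussian-in-linear-sv
  vertical profiles and diel vertical migration between a daytime and a
  nighttime residence depth, switched by the same solar-altitude
  computation the analysis uses;
* monthly environmental series (SST, upwelling wind, chlorophyll) built
  as mean level + seasonal sinusoid + linear trend + i.i.d. Gaussian
  noise.

Every generated object carries ground-truth labels (layer class, true
per-column centre depth, true biomass-weighted position) so parameter-
recovery tests can score the pipeline against what was simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diel import solar_altitude
from .echo import Echogram

__all__ = [
    "EchogramConfig",
    "LayerSpec",
    "EnvSeriesConfig",
    "GroundTruth",
    "generate_echogram",
    "generate_env_series",
    "survey_track",
]

#: trophic Sv bands the simulated layers must respect, dB
GROUP_BANDS = {"plankton": (-80.0, -65.0), "fish": (-65.0, -20.0)}


# ---------------------------------------------------------------------------
# configs


@dataclass
class EchogramConfig:
    """Geometry and noise floor of one simulated echogram."""

    track: pd.DataFrame  # columns: lat, lon, time (UTC) — one row per column
    bottom_depth: np.ndarray  # m per column
    depth_max: float = 150.0
    depth_step: float = 1.0
    noise_floor_db: float = -100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.bottom_depth = np.asarray(self.bottom_depth, dtype=float)
        if self.depth_step <= 0:
            raise ValueError("depth_step must be positive")
        if len(self.track) < 1:
            raise ValueError("track needs at least one column")
        if len(self.bottom_depth) != len(self.track):
            raise ValueError("bottom_depth length must match the track")
        lats = self.track["lat"].to_numpy(dtype=float)
        lons = self.track["lon"].to_numpy(dtype=float)
        if np.any(np.abs(lats) > 90) or np.any(np.abs(lons) > 180):
            raise ValueError("track coordinates out of range")
        t = pd.DatetimeIndex(self.track["time"])
        if len(t) > 1 and not t.is_monotonic_increasing or t.has_duplicates:
            raise ValueError("track timestamps must be strictly increasing")

    @property
    def n_columns(self) -> int:
        return len(self.track)


@dataclass
class LayerSpec:
    """One sound-scattering layer or school.

    ``thickness`` is the Gaussian sigma (m) of the vertical profile in
    linear sv, truncated at +-2 sigma.  ``occupancy`` is the fraction of
    track columns the layer occupies; with ``lat_center`` set, occupancy
    is modulated by a Gaussian in latitude (sd ``lat_sd``) so the layer
    has a spatial centre that barycenter analyses can recover.
    """

    group: str  # "plankton" or "fish"
    sv_mean_db: float
    sv_sd_db: float = 0.0
    depth_day: float = 60.0
    depth_night: float = 15.0
    thickness: float = 5.0
    occupancy: float = 1.0
    lat_center: float | None = None
    lat_sd: float = 0.5
    name: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUP_BANDS:
            raise ValueError(f"unknown group {self.group!r}")
        lo, hi = GROUP_BANDS[self.group]
        if not (lo <= self.sv_mean_db < hi):
            raise ValueError(
                f"layer {self.label}: sv_mean_db {self.sv_mean_db} outside "
                f"the {self.group} band [{lo}, {hi})"
            )
        if self.thickness <= 0:
            raise ValueError(f"layer {self.label}: thickness must be positive")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"layer {self.label}: occupancy must be in [0, 1]")

    @property
    def label(self) -> str:
        return self.name or self.group


@dataclass
class EnvSeriesConfig:
    """Skeleton of a monthly environmental series."""

    variable: str  # SST, UW or SSC
    n_years: int
    mean_level: float
    seasonal_amplitude: float = 0.0
    trend_per_decade: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    start_year: int = 1995
    area: str = ""

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What was actually simulated, for parameter-recovery scoring.

    ``table`` holds one row per (layer, occupied column) with the true
    centre depth; ``masks`` maps layer label -> boolean (depth, column)
    grid of emitted in-band cells; ``positions`` maps layer label ->
    (lat, lon) of the true column-integral-weighted position.
    """

    table: pd.DataFrame
    masks: dict[str, np.ndarray]
    positions: dict[str, tuple[float, float]]

    @property
    def empty(self) -> bool:
        return self.table.empty

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# echogram generation


def generate_echogram(
    config: EchogramConfig, layers: Sequence[LayerSpec] = ()
) -> tuple[Echogram, GroundTruth]:
    """Render layers onto a noise-floor grid and report the ground truth.

    Each layer contributes a Gaussian (in linear sv) depth profile centred
    on its day or night residence depth, chosen per column from the solar
    altitude at that column's time and position (sun up -> day depth).
    Contributions add in the linear domain on top of the noise floor; a
    cell belongs to a layer's ground-truth mask when the layer's emitted
    level stays inside its trophic band — profile tails that would leak
    below the band floor are cut rather than emitted out-of-band, and dB
    jitter is clipped to the band.
    """
    depths = np.arange(config.depth_step / 2.0, config.depth_max, config.depth_step)
    n_depth, n_col = len(depths), config.n_columns
    for layer in layers:
        if max(layer.depth_day, layer.depth_night) + layer.thickness > config.depth_max:
            raise ValueError(
                f"layer {layer.label}: centre + thickness exceeds depth_max "
                f"({config.depth_max} m)"
            )

    rng = np.random.default_rng(config.seed)
    lats = config.track["lat"].to_numpy(dtype=float)
    lons = config.track["lon"].to_numpy(dtype=float)
    times = pd.DatetimeIndex(config.track["time"])

    alt = np.atleast_1d(solar_altitude(lats, lons, times.values))
    is_day = alt > 0.0

    sv_lin = np.full((n_depth, n_col), 10.0 ** (config.noise_floor_db / 10.0))
    masks: dict[str, np.ndarray] = {}
    positions: dict[str, tuple[float, float]] = {}
    rows: list[dict] = []

    for k, layer in enumerate(layers):
        label = layer.name or f"{layer.group}_{k}"
        lo, hi = GROUP_BANDS[layer.group]

        if layer.lat_center is None:
            p_occ = np.full(n_col, layer.occupancy)
        else:
            p_occ = layer.occupancy * np.exp(
                -0.5 * ((lats - layer.lat_center) / layer.lat_sd) ** 2
            )
        occupied = rng.random(n_col) < p_occ

        center = np.where(is_day, layer.depth_day, layer.depth_night)
        sigma = layer.thickness
        zdiff = depths[:, None] - center[None, :]
        shape = np.exp(-0.5 * (zdiff / sigma) ** 2)
        in_extent = np.abs(zdiff) <= 2.0 * sigma

        peak_db = layer.sv_mean_db + (
            rng.normal(0.0, layer.sv_sd_db, size=(n_depth, n_col))
            if layer.sv_sd_db > 0
            else 0.0
        )
        contrib_db = peak_db + 10.0 * np.log10(np.where(shape > 0, shape, 1e-300))
        # keep the emitted layer inside its trophic band
        contrib_db = np.minimum(contrib_db, np.nextafter(hi, -np.inf))
        in_band = contrib_db >= lo

        below_bottom = depths[:, None] > config.bottom_depth[None, :]
        mask = in_extent & in_band & occupied[None, :] & ~below_bottom
        contrib_lin = np.where(mask, 10.0 ** (contrib_db / 10.0), 0.0)
        sv_lin += contrib_lin

        masks[label] = mask
        col_w = contrib_lin.sum(axis=0)
        if col_w.sum() > 0:
            positions[label] = (
                float((col_w * lats).sum() / col_w.sum()),
                float((col_w * lons).sum() / col_w.sum()),
            )
        else:
            positions[label] = (float("nan"), float("nan"))
        for j in np.flatnonzero(occupied):
            rows.append(
                {
                    "layer": label,
                    "group": layer.group,
                    "column": int(j),
                    "center_depth": float(center[j]),
                    "lat": float(lats[j]),
                    "lon": float(lons[j]),
                    "is_day": bool(is_day[j]),
                }
            )

    sv_db = 10.0 * np.log10(sv_lin)
    sv_db[depths[:, None] > config.bottom_depth[None, :]] = config.noise_floor_db

    echogram = Echogram(
        sv=sv_db,
        depths=depths,
        times=times,
        lats=lats,
        lons=lons,
        bottom_depth=config.bottom_depth,
    )
    truth = GroundTruth(
        table=pd.DataFrame(
            rows,
            columns=[
                "layer",
                "group",
                "column",
                "center_depth",
                "lat",
                "lon",
                "is_day",
            ],
        ),
        masks=masks,
        positions=positions,
    )
    return echogram, truth


# ---------------------------------------------------------------------------
# environmental series


def generate_env_series(config: EnvSeriesConfig):
    """Monthly series: mean + seasonal sinusoid + linear trend + noise.

    The trend enters as ``trend_per_decade / 120`` per month; the seasonal
    term is ``amplitude * sin(2*pi*m/12)`` with m the month index from the
    series start.  Reproducible for a fixed seed.
    """
    from .trends import EnvSeries  # local import to avoid cycle at import time

    n = 12 * config.n_years
    m = np.arange(n, dtype=float)
    rng = np.random.default_rng(config.seed)
    values = (
        config.mean_level
        + config.seasonal_amplitude * np.sin(2.0 * np.pi * m / 12.0)
        + (config.trend_per_decade / 120.0) * m
        + (rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0)
    )
    times = pd.date_range(
        start=f"{config.start_year}-01-01", periods=n, freq="MS"
    )
    return EnvSeries(
        variable=config.variable, times=times, values=values, area=config.area
    )


# ---------------------------------------------------------------------------
# track helper


def survey_track(
    n_columns: int,
    lat_start: float,
    lat_end: float,
    lon: float = -17.0,
    start_time: str | pd.Timestamp = "1995-11-10 06:00:00",
    duration_hours: float = 48.0,
) -> pd.DataFrame:
    """A straight meridional transect sampled uniformly in time.

    Spanning ~2 days guarantees both day and night columns, the condition
    every diel analysis needs.
    """
    t0 = pd.Timestamp(start_time)
    times = t0 + pd.to_timedelta(
        np.linspace(0.0, duration_hours * 3600.0, n_columns), unit="s"
    )
    return pd.DataFrame(
        {
            "lat": np.linspace(lat_start, lat_end, n_columns),
            "lon": np.full(n_columns, lon),
            "time": times,
        }
    )
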