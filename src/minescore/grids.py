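"""Grid data model and raster/vector map algebra.

Everything downstream computes on :class:`Grid` objects sharing a single
:class:`GridSpec`: a planar, north-up, 30 m lattice with the origin at the
top-left corner (row 0 is the northernmost row).  Coordinates are metres in
an unspecified projected CRS; no geographic math is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .constants import FEATURE_CLASSES, MINERALS, METHODS

__all__ = [
    "GridSpec", "Grid", "MineFeature", "StationSeries",
    "minmax_normalize", "rasterize", "distance_to_features", "graded_buffer",
]


@dataclass(frozen=True)
class GridSpec:
    """Shape and georeferencing of the common lattice."""

    n_rows: int
    n_cols: int
    cell_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0  # y of the TOP-left corner; y decreases with row
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full lattice extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (X, Y) of cell-centre coordinates, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col


@dataclass
class Grid:
    """A single-band raster: values on a :class:`GridSpec` lattice."""

    spec: GridSpec
    values: np.ndarray
    nodata: float | int | None = None
    kind: str = "continuous"  # or "categorical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown grid kind {self.kind!r}")

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        if self.nodata is None:
            return np.ones(self.spec.shape, dtype=bool)
        v = self.values
        if np.issubdtype(v.dtype, np.floating) and np.isnan(self.nodata):
            return ~np.isnan(v)
        return v != self.nodata

    def like(self, values: np.ndarray, kind: str | None = None,
             nodata=None) -> "Grid":
        return Grid(self.spec, values, nodata=nodata,
                    kind=kind or self.kind)

    def copy(self) -> "Grid":
        return Grid(self.spec, self.values.copy(), self.nodata, self.kind)


@dataclass
class MineFeature:
    """A mapped mine element: geometry plus its controlled-vocabulary tags."""

    geometry: BaseGeometry
    feature_class: str
    mineral: str = "non_metal"
    method: str = "open_pit"

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        if self.mineral not in MINERALS:
            raise ValueError(f"unknown mineral {self.mineral!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not self.geometry.is_valid:
            raise ValueError("invalid geometry")


@dataclass
class StationSeries:
    """Monthly meteorology at one station: 12 records, March-first order."""

    station_id: str
    x: float
    y: float
    months: Sequence[int] = field(default_factory=list)
    rainfall: Sequence[float] = field(default_factory=list)       # mm / month
    temperature: Sequence[float] = field(default_factory=list)    # deg C
    solar_radiation: Sequence[float] = field(default_factory=list)  # MJ m-2 / month
    aqi: Sequence[float] = field(default_factory=list)
    wind_speed: Sequence[float] = field(default_factory=list)     # m s-1

    def __post_init__(self) -> None:
        n = len(self.months)
        if n != 12 or sorted(self.months) != list(range(1, 13)):
            raise ValueError(
                f"station {self.station_id!r}: need exactly the 12 calendar "
                f"months, got {list(self.months)}")
        for name in ("rainfall", "temperature", "solar_radiation", "aqi",
                     "wind_speed"):
            if len(getattr(self, name)) != 12:
                raise ValueError(
                    f"station {self.station_id!r}: {name} needs 12 values")
        if any(w <= 0 for w in self.wind_speed):
            raise ValueError(
                f"station {self.station_id!r}: wind_speed must be positive")

    def month_value(self, variable: str, month: int) -> float:
        idx = list(self.months).index(month)
        return float(getattr(self, variable)[idx])


# ---------------------------------------------------------------------------
# map algebra
# ---------------------------------------------------------------------------

def minmax_normalize(g: Grid) -> Grid:
    """Rescale a continuous grid onto [0, 1] over its valid cells.

    Constant grids map to all zeros (degenerate-range convention), where
    "constant" allows a relative spread up to 1e-12 so that float summation
    noise in a physically uniform field is not blown up to full scale;
    nodata cells are preserved.
    """
    valid = g.valid
    if not valid.any():
        raise ValueError("cannot normalize an empty / all-nodata grid")
    v = np.asarray(g.values, dtype=float)
    lo = v[valid].min()
    hi = v[valid].max()
    out = np.zeros_like(v)
    if hi - lo > 1e-12 * max(abs(lo), abs(hi), 1.0):
        out[valid] = (v[valid] - lo) / (hi - lo)
    if g.nodata is not None:
        out[~valid] = np.nan
        return Grid(g.spec, out, nodata=np.nan, kind="continuous")
    return Grid(g.spec, out, kind="continuous")


def _geometries(features: Iterable) -> list[BaseGeometry]:
    geoms = []
    for f in features:
        geoms.append(f.geometry if isinstance(f, MineFeature) else f)
    return geoms


def rasterize(features: Iterable, spec: GridSpec, burn_value: float = 1.0) -> Grid:
    """Burn geometries onto the lattice with the cell-centre rule.

    A cell takes ``burn_value`` iff its centre lies on or inside any
    geometry; all other cells are 0.
    """
    geoms = _geometries(features)
    out = np.zeros(spec.shape, dtype=float)
    if not geoms:
        return Grid(spec, out)
    xmin, ymin, xmax, ymax = spec.bounds
    scene = shapely.box(xmin, ymin, xmax, ymax)
    X, Y = spec.cell_centres()
    pts = shapely.points(X.ravel(), Y.ravel())
    hit = np.zeros(pts.shape, dtype=bool)
    for geom in geoms:
        if not geom.intersects(scene):
            warnings.warn("geometry outside scene extent; nothing burned",
                          stacklevel=2)
            continue
        hit |= shapely.covers(geom, pts)
    out.ravel()[hit] = burn_value
    return Grid(spec, out)


def distance_to_features(features: Iterable, spec: GridSpec) -> Grid:
    """Euclidean distance (m) from each cell centre to the nearest feature.

    Distance is 0 on the boundary of or inside a geometry.
    """
    geoms = _geometries(features)
    if not geoms:
        raise ValueError("distance_to_features requires at least one feature")
    union = shapely.union_all(geoms)
    X, Y = spec.cell_centres()
    pts = shapely.points(X.ravel(), Y.ravel())
    d = shapely.distance(pts, union).reshape(spec.shape)
    return Grid(spec, d)


def graded_buffer(features: Iterable, breaks: Sequence[float],
                  spec: GridSpec) -> Grid:
    """Concentric impact rings around source features.

    With k = len(breaks) rings, ring i covers distances in
    (breaks[i-1], breaks[i]] (ring 1 includes distance 0) and takes the value
    (k - i + 1) / k; cells beyond the outermost break are 0.  Values are
    therefore non-increasing with distance.
    """
    breaks = list(breaks)
    if not breaks or any(b <= 0 for b in breaks) or \
            any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly ascending and positive")
    geoms = _geometries(features)
    k = len(breaks)
    if not geoms:
        return Grid(spec, np.zeros(spec.shape))
    d = distance_to_features(geoms, spec).values
    # ring index: number of breaks strictly below d, +1  (d=0 -> ring 1)
    ring = np.searchsorted(breaks, d, side="left") + 1
    out = np.where(ring <= k, (k - ring + 1) / k, 0.0)
    return Grid(spec, out)
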