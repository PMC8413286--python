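"""The five sub-indices and composite of the national eco-environment
status standard (HJ 192-2015 style), on the common lattice.

    EI = 0.35 * biological abundance + 0.25 * vegetation coverage
       + 0.15 * river density + 0.15 * (1 - land stress)
       + 0.10 * (1 - pollution loading)

Each sub-index is min-max normalized onto [0, 1] before entering the
composite, so EI itself lies in [0, 1] and is classified into five levels
(very bad .. very good) with equal-interval breaks by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry.base import BaseGeometry

from .constants import (A_ERO, A_LAK, A_RES, A_RIV, CLASS_BREAKS,
                        CONSTRUCTION_LAND, EI_WEIGHTS, ERODIBLE_SOILS,
                        HABITAT_WEIGHTS, LANDUSE_WEIGHTS, SOIL_NAMES,
                        WATER_WETLAND, WOODLAND)
from .grids import Grid, GridSpec, minmax_normalize

__all__ = [
    "EiWeights", "HabitatWeights", "BiFactors", "RiverDensityParams",
    "LandStressParams", "ndvi_from_bands", "vegetation_coverage_index",
    "habitat_quality", "biodiversity_index", "biological_abundance_index",
    "river_density_index", "classify_erosion", "land_stress_index",
    "pollution_loading_index", "ei", "classify_five",
]

EROSION_NONE = 0
EROSION_OTHER = 1   # moderate erosion / construction land / other stress
EROSION_SEVERE = 2


@dataclass(frozen=True)
class EiWeights:
    bio_abundance: float = EI_WEIGHTS["biological_abundance"]
    vegetation: float = EI_WEIGHTS["vegetation_coverage"]
    river_density: float = EI_WEIGHTS["river_density"]
    land_stress: float = EI_WEIGHTS["land_stress"]
    pollution_load: float = EI_WEIGHTS["pollution_loading"]

    def __post_init__(self) -> None:
        total = (self.bio_abundance + self.vegetation + self.river_density
                 + self.land_stress + self.pollution_load)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"EI weights must sum to 1, got {total}")


@dataclass(frozen=True)
class HabitatWeights:
    landuse: Mapping[int, float] = field(
        default_factory=lambda: dict(LANDUSE_WEIGHTS))
    habitat: Mapping[int, float] = field(
        default_factory=lambda: dict(HABITAT_WEIGHTS))

    @property
    def max_product(self) -> float:
        return max(self.landuse[h // 10] * w for h, w in self.habitat.items()
                   if h // 10 in self.landuse)


@dataclass
class BiFactors:
    """Normalized drivers of the biodiversity index, all in [0, 1]."""
    npp_mean: Grid
    f_pre: Grid   # normalized annual / window precipitation
    f_tem: Grid   # normalized temperature
    f_alt: Grid   # normalized elevation (penalizes altitude)


@dataclass(frozen=True)
class RiverDensityParams:
    a_riv: float = A_RIV
    a_lak: float = A_LAK
    a_res: float = A_RES
    window_radius: float = 1000.0  # metres

    def __post_init__(self) -> None:
        if min(self.a_riv, self.a_lak, self.a_res) <= 0:
            raise ValueError("coefficients must be positive")


@dataclass(frozen=True)
class LandStressParams:
    a_ero: float = A_ERO
    weight_severe: float = 0.4
    weight_other: float = 0.2    # moderate erosion / construction / other
    weight_none: float = 0.0
    window_radius: float = 1000.0


def ndvi_from_bands(nir: Grid, red: Grid) -> Grid:
    """(NIR - R) / (NIR + R); zero-sum cells become nodata (NaN)."""
    if nir.spec != red.spec:
        raise ValueError("misaligned NIR / red grids")
    a = np.asarray(nir.values, float)
    b = np.asarray(red.values, float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("reflectances must be non-negative")
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (a - b) / np.where(denom > 0, denom, 1.0),
                       np.nan)
    return Grid(nir.spec, out, nodata=np.nan)


def vegetation_coverage_index(ndvi: Grid) -> Grid:
    """Min-max normalized NDVI."""
    return minmax_normalize(ndvi)


def habitat_quality(land_use: Grid, habitat: Grid,
                    weights: HabitatWeights | None = None) -> Grid:
    """Per-pixel habitat quality: class weight x subtype weight, scaled by
    the maximum attainable product so the best habitat scores 1."""
    weights = weights or HabitatWeights()
    if habitat.spec != land_use.spec:
        raise ValueError("misaligned land-use / habitat grids")
    out = np.zeros(land_use.spec.shape)
    for sub in np.unique(habitat.values[habitat.valid]).astype(int):
        if sub not in weights.habitat:
            raise KeyError(f"unknown habitat subtype code {sub}")
        cls = sub // 10
        if cls not in weights.landuse:
            raise KeyError(f"unknown land-use class code {cls}")
        out[habitat.values == sub] = (weights.landuse[cls]
                                      * weights.habitat[sub])
    return Grid(land_use.spec, out / weights.max_product)


def biodiversity_index(f: BiFactors, normalize: bool = True) -> Grid:
    """BI = NPP_mean * F_pre * F_tem * (1 - F_alt)."""
    spec = f.npp_mean.spec
    for g in (f.f_pre, f.f_tem, f.f_alt):
        if g.spec != spec:
            raise ValueError("misaligned biodiversity factor grids")
    bi = (np.asarray(f.npp_mean.values, float) * f.f_pre.values
          * f.f_tem.values * (1.0 - np.asarray(f.f_alt.values, float)))
    g = Grid(spec, bi)
    return minmax_normalize(g) if normalize else g


def biological_abundance_index(bi: Grid, hq: Grid,
                               normalize: bool = True) -> Grid:
    """(BI + HQ) / 2, min-max normalized by default."""
    if bi.spec != hq.spec:
        raise ValueError("misaligned BI / HQ grids")
    g = Grid(bi.spec, (np.asarray(bi.values, float) + hq.values) / 2.0)
    return minmax_normalize(g) if normalize else g


def _disk_kernel(radius_m: float, cell_size: float) -> np.ndarray:
    r = int(np.floor(radius_m / cell_size))
    if r < 1:
        raise ValueError("window radius must exceed the cell size")
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return ((xx ** 2 + yy ** 2) * cell_size ** 2 <= radius_m ** 2).astype(float)


def window_mean(values: np.ndarray, radius_m: float,
                cell_size: float) -> np.ndarray:
    """Mean over a circular moving window, truncated at scene edges.

    Direct (non-FFT) summation so results agree with a looped oracle to
    machine precision.
    """
    k = _disk_kernel(radius_m, cell_size)
    s = ndimage.convolve(values.astype(float), k, mode="constant", cval=0.0)
    n = ndimage.convolve(np.ones_like(values, dtype=float), k,
                         mode="constant", cval=0.0)
    return s / n


def river_length_grid(rivers: Sequence[BaseGeometry], spec: GridSpec) -> np.ndarray:
    """Exact river length (m) per cell: each polyline is clipped to every
    cell box its bounding boxes touch."""
    out = np.zeros(spec.shape)
    cs = spec.cell_size
    x0, y0 = spec.origin_x, spec.origin_y
    for line in rivers:
        coords = np.asarray(line.coords)
        for (ax, ay), (bx, by) in zip(coords[:-1], coords[1:]):
            seg = shapely.linestrings([[ax, ay], [bx, by]])
            c0 = max(int((min(ax, bx) - x0) // cs), 0)
            c1 = min(int((max(ax, bx) - x0) // cs), spec.n_cols - 1)
            r0 = max(int((y0 - max(ay, by)) // cs), 0)
            r1 = min(int((y0 - min(ay, by)) // cs), spec.n_rows - 1)
            for r in range(r0, r1 + 1):
                for c in range(c0, c1 + 1):
                    cell = shapely.box(x0 + c * cs, y0 - (r + 1) * cs,
                                       x0 + (c + 1) * cs, y0 - r * cs)
                    piece = seg.intersection(cell)
                    if not piece.is_empty:
                        out[r, c] += piece.length
    return out


def river_density_index(rivers: Sequence[BaseGeometry],
                        lakes: Sequence[BaseGeometry],
                        resources_amount: float,
                        spec: GridSpec,
                        params: RiverDensityParams | None = None,
                        normalize: bool = True) -> Grid:
    """Water abundance in a circular moving window.

    Per window: (a_riv * river_length/area + a_lak * lake_area/area
    + a_res * resources/area) / 3, where ``resources_amount`` is a
    scene-level scalar spread uniformly (no spatial resource data exists).
    """
    params = params or RiverDensityParams()
    if params.window_radius <= spec.cell_size:
        raise ValueError("window radius must exceed the cell size")
    cell_area = spec.cell_size ** 2
    riv_len = river_length_grid(rivers, spec) if rivers else np.zeros(spec.shape)
    lake_area = np.zeros(spec.shape)
    if lakes:
        from .grids import rasterize
        lake_area = rasterize(lakes, spec).values * cell_area
    scene_area = spec.n_rows * spec.n_cols * cell_area
    res_per_area = resources_amount / scene_area
    raw = (params.a_riv * window_mean(riv_len, params.window_radius,
                                      spec.cell_size) / cell_area
           + params.a_lak * window_mean(lake_area, params.window_radius,
                                        spec.cell_size) / cell_area
           + params.a_res * res_per_area) / 3.0
    g = Grid(spec, raw)
    return minmax_normalize(g) if normalize else g


def classify_erosion(land_use: Grid, soil: Grid, veg_frac: Grid) -> Grid:
    """Erosion class per pixel from the standard's proxy rules.

    Severe: industrial/mining (construction-class) land on the highly
    erodible cinnamon or loess soils, or vegetation fraction < 0.30.
    None: water bodies and woodland, or vegetation fraction > 0.50.
    Everything else carries the single 0.2-weight class.  Severe takes
    precedence over the non-eroded rule where both apply.
    """
    for g in (soil, veg_frac):
        if g.spec != land_use.spec:
            raise ValueError("misaligned erosion input grids")
    known = set(SOIL_NAMES)
    codes = set(np.unique(soil.values[soil.valid]).astype(int))
    if codes - known:
        raise KeyError(f"unknown soil codes {sorted(codes - known)}")
    lu = land_use.values
    erodible = np.isin(soil.values, list(ERODIBLE_SOILS))
    severe = ((lu == CONSTRUCTION_LAND) & erodible) | (veg_frac.values < 0.30)
    none = np.isin(lu, [WATER_WETLAND, WOODLAND]) | (veg_frac.values > 0.50)
    out = np.full(land_use.spec.shape, EROSION_OTHER, dtype=np.int64)
    out[none] = EROSION_NONE
    out[severe] = EROSION_SEVERE
    return Grid(land_use.spec, out, kind="categorical")


def land_stress_index(erosion: Grid,
                      params: LandStressParams | None = None,
                      normalize: bool = True) -> Grid:
    """Area-weighted stress in a circular moving window, Eq.-21 style:
    a_ero * (0.4 * severe fraction + 0.2 * other fraction) per window,
    min-max normalized by default."""
    params = params or LandStressParams()
    w = np.select(
        [erosion.values == EROSION_SEVERE, erosion.values == EROSION_OTHER],
        [params.weight_severe, params.weight_other], params.weight_none)
    raw = params.a_ero * window_mean(w, params.window_radius,
                                     erosion.spec.cell_size)
    g = Grid(erosion.spec, raw)
    if not normalize:
        return g
    return minmax_normalize(g) if raw.max() > raw.min() else Grid(
        erosion.spec, np.zeros(erosion.spec.shape))


def pollution_loading_index(aqi: Grid) -> Grid:
    """Min-max normalized (kriged) AQI surface."""
    if (np.asarray(aqi.values, float)[aqi.valid] < 0).any():
        raise ValueError("AQI must be non-negative")
    return minmax_normalize(aqi)


def ei(bio_abundance: Grid, vegetation: Grid, river_density: Grid,
       land_stress: Grid, pollution_loading: Grid,
       weights: EiWeights | None = None) -> Grid:
    """The composite eco-environmental status index on [0, 1]."""
    weights = weights or EiWeights()
    spec = bio_abundance.spec
    grids = (vegetation, river_density, land_stress, pollution_loading)
    if any(g.spec != spec for g in grids):
        raise ValueError("misaligned index grids")
    score = (weights.bio_abundance * np.asarray(bio_abundance.values, float)
             + weights.vegetation * vegetation.values
             + weights.river_density * river_density.values
             + weights.land_stress * (1.0 - np.asarray(land_stress.values, float))
             + weights.pollution_load * (1.0 - np.asarray(pollution_loading.values, float)))
    return Grid(spec, score)


def classify_five(score: Grid | np.ndarray,
                  breaks: Sequence[float] = CLASS_BREAKS) -> Grid | np.ndarray:
    """Five-level classification of a [0, 1] score.

    Bins are [0, b1], (b1, b2], ..., (b4, 1]; a score exactly on a break
    falls in the lower bin.  Codes 1 (very bad) .. 5 (very good).
    """
    breaks = list(breaks)
    if len(breaks) != 4 or any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])) \
            or breaks[0] <= 0 or breaks[-1] >= 1:
        raise ValueError("need 4 strictly ascending breaks inside (0, 1)")
    values = score.values if isinstance(score, Grid) else np.asarray(score)
    cls = np.searchsorted(breaks, values, side="left") + 1
    if isinstance(score, Grid):
        return Grid(score.spec, cls.astype(np.int64), kind="categorical")
    return cls.astype(np.int64)
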