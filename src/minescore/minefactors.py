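"""The four mine-impact factor layers and the mining / non-mining split.

The improved evaluation system adds, on top of the five standard indices:

* air pollution range — 1/wind-speed within 50 m of open pits and
  concentrator plants (atmospheric dilution makes impact reciprocal in wind);
* solid waste area — ore piles, coal piles and dumping sites;
* geologic hazard range — underground stopes and coal piles;
* soil pollution buffers — graded distance rings around non-metal workings
  and coal piles (30/200/1000 m) and around metal-mine features
  (50/100/300/500 m), reflecting the measured spread of heavy metals.

The scene is split into a mining region (within 1000 m of any mine feature
or protection area) and a non-mining region; the two regions are scored by
separately trained models downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry

from .grids import (Grid, GridSpec, MineFeature, distance_to_features,
                    graded_buffer, rasterize)

__all__ = ["BufferSpec", "RegionMask", "air_pollution_range",
           "solid_waste_area", "geologic_hazard_range",
           "soil_pollution_buffer", "region_split"]

MINING = 1
NON_MINING = 0


@dataclass(frozen=True)
class BufferSpec:
    non_metal_breaks: tuple[float, ...] = (30.0, 200.0, 1000.0)
    metal_breaks: tuple[float, ...] = (50.0, 100.0, 300.0, 500.0)
    air_radius: float = 50.0
    region_radius: float = 1000.0

    def __post_init__(self) -> None:
        for breaks in (self.non_metal_breaks, self.metal_breaks):
            if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])) or \
                    min(breaks) <= 0:
                raise ValueError("break lists must be strictly ascending and positive")


@dataclass
class RegionMask:
    """Partition of the scene into mining (1) and non-mining (0) cells."""

    grid: Grid

    @property
    def mining(self) -> np.ndarray:
        return self.grid.values == MINING

    @property
    def non_mining(self) -> np.ndarray:
        return self.grid.values == NON_MINING


def _select(features: Sequence[MineFeature], classes=None, mineral=None,
            method=None) -> list[MineFeature]:
    out = []
    for f in features:
        if classes is not None and f.feature_class not in classes:
            continue
        if mineral is not None and f.mineral != mineral:
            continue
        if method is not None and f.method != method:
            continue
        out.append(f)
    return out


def air_pollution_range(features: Sequence[MineFeature], wind_speed: Grid,
                        spec: GridSpec,
                        b: BufferSpec = BufferSpec()) -> Grid:
    """1/wind inside the 50 m dust halo of open pits and concentrator
    plants, 0 elsewhere; min-max normalized over the in-halo support."""
    if wind_speed.spec != spec:
        raise ValueError("misaligned wind-speed grid")
    w = np.asarray(wind_speed.values, float)
    if (w <= 0).any():
        raise ValueError("wind speed must be strictly positive everywhere")
    sources = _select(features, classes={"open_pit", "concentrator_plant"})
    out = np.zeros(spec.shape)
    if not sources:
        return Grid(spec, out)
    d = distance_to_features(sources, spec).values
    mask = d <= b.air_radius
    if not mask.any():
        return Grid(spec, out)
    raw = 1.0 / w[mask]
    lo, hi = raw.min(), raw.max()
    # constant-support convention: the halo stays visible at 1.0
    out[mask] = (raw - lo) / (hi - lo) if hi > lo else 1.0
    return Grid(spec, out)


def solid_waste_area(features: Sequence[MineFeature],
                     spec: GridSpec) -> Grid:
    """1 inside ore piles, coal piles and dumping sites; 0 elsewhere."""
    waste = _select(features, classes={"ore_pile", "coal_pile", "dumping_site"})
    return rasterize(waste, spec, burn_value=1.0)


def geologic_hazard_range(features: Sequence[MineFeature],
                          spec: GridSpec) -> Grid:
    """1 inside underground stopes and coal piles; 0 elsewhere."""
    hazard = (_select(features, classes={"stope"}, method="underground")
              + _select(features, classes={"coal_pile"}))
    return rasterize(hazard, spec, burn_value=1.0)


def soil_pollution_buffer(features: Sequence[MineFeature], spec: GridSpec,
                          b: BufferSpec = BufferSpec()) -> tuple[Grid, Grid]:
    """(non-metal, metal) graded soil-pollution buffers.

    Non-metal: rings around non-metal mine workings (stopes, open pits,
    concentrator plants) and all coal piles at 30/200/1000 m.  Metal: rings
    around every metal-mine feature at 50/100/300/500 m.  Buffers grow from
    the feature geometry itself, not its centroid.
    """
    non_metal_sources = (
        _select(features, classes={"stope", "open_pit", "concentrator_plant"},
                mineral="non_metal")
        + _select(features, classes={"coal_pile"}))
    metal_sources = _select(features, mineral="metal")
    nm = graded_buffer(non_metal_sources, b.non_metal_breaks, spec) \
        if non_metal_sources else Grid(spec, np.zeros(spec.shape))
    mt = graded_buffer(metal_sources, b.metal_breaks, spec) \
        if metal_sources else Grid(spec, np.zeros(spec.shape))
    return nm, mt


def region_split(features: Sequence[MineFeature],
                 protection_areas: Sequence[BaseGeometry] | None,
                 spec: GridSpec,
                 b: BufferSpec = BufferSpec()) -> RegionMask:
    """Mining region: within 1000 m of any mine feature, or inside / within
    1000 m of a protection area; everything else non-mining."""
    mining = np.zeros(spec.shape, dtype=bool)
    sources: list = list(features)
    if protection_areas:
        sources += list(protection_areas)
    if sources:
        d = distance_to_features(sources, spec).values
        mining = d <= b.region_radius
    values = np.where(mining, MINING, NON_MINING).astype(np.int64)
    return RegionMask(Grid(spec, values, kind="categorical"))
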