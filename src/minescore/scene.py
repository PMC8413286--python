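"""Synthetic study scenes.

Generates complete, self-consistent inputs for the whole pipeline — terrain,
categorical land use with habitat subtypes, soils, monthly NDVI, rivers and
lakes, station meteorology with a warm-temperate monsoon seasonal cycle
(rainfall concentrated in July-September), and clustered mine features of
all seven classes — plus scored sample points mirroring the study's
sampling design (700 non-mining + 100 mining points).

Everything is drawn from one ``numpy`` Generator seeded by the config, so a
fixed seed reproduces the scene bit for bit.  Mining-point "field scores"
come from an explicit documented ground-truth function (EI minus equal
penalties on the four mine-impact layers) plus Gaussian noise, which makes
model recovery by the learning stage well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point

from .constants import (ARABLE_LAND, CONSTRUCTION_LAND, GRASSLAND,
                        SEASON_MONTHS, SOIL_CINNAMON, SOIL_FLUVO_AQUIC,
                        SOIL_LOESS, SOIL_NEW, STUDY_MONTHS, UNUTILIZED_LAND,
                        WATER_WETLAND, WOODLAND)
from .grids import Grid, GridSpec, MineFeature, StationSeries

__all__ = ["SceneConfig", "Scene", "ScoredSample", "make_scene",
           "make_samples", "make_seasons", "write_scene"]

DEFAULT_MIXTURE: Mapping[int, float] = {
    WOODLAND: 0.30, GRASSLAND: 0.20, ARABLE_LAND: 0.25,
    CONSTRUCTION_LAND: 0.10, WATER_WETLAND: 0.05, UNUTILIZED_LAND: 0.10,
}

# quantile order from low to high terrain when carving land-use patches
_LANDUSE_ORDER = (WATER_WETLAND, ARABLE_LAND, CONSTRUCTION_LAND,
                  GRASSLAND, UNUTILIZED_LAND, WOODLAND)

# habitat subtype mixtures within each class (subtype code -> share)
_HABITAT_MIX = {
    WOODLAND: {11: 0.60, 12: 0.25, 13: 0.15},
    GRASSLAND: {21: 0.40, 22: 0.40, 23: 0.20},
    WATER_WETLAND: {31: 0.50, 32: 0.40, 33: 0.10},
    ARABLE_LAND: {41: 0.30, 42: 0.70},
    CONSTRUCTION_LAND: {51: 0.30, 52: 0.40, 53: 0.30},
    UNUTILIZED_LAND: {63: 0.50, 65: 0.50},
}

_NDVI_BASE = {WOODLAND: 0.70, GRASSLAND: 0.50, ARABLE_LAND: 0.45,
              CONSTRUCTION_LAND: 0.15, WATER_WETLAND: 0.05,
              UNUTILIZED_LAND: 0.20}

# monthly rainfall shares: ~70 % of the annual total falls Jul-Sep
_RAIN_SHARE = {7: 0.28, 8: 0.24, 9: 0.18}
_RAIN_REST = (1.0 - sum(_RAIN_SHARE.values())) / 9


@dataclass(frozen=True)
class SceneConfig:
    seed: int = 0
    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 30.0
    landuse_mixture: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MIXTURE))
    n_stations: int = 8
    n_mine_sites: int = 6
    metal_fraction: float = 0.4     # share of mine sites that are metal mines
    months: tuple[int, ...] = STUDY_MONTHS
    noise_sd: float = 0.05          # sd of synthetic field-score noise
    annual_rainfall_mm: float = 583.0
    mean_temperature_c: float = 14.5
    resources_amount: float = 5.0e7  # scene-level water-resources scalar

    def __post_init__(self) -> None:
        total = sum(self.landuse_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"land-use mixture must sum to 1, got {total}")
        if sorted(self.months) != sorted(set(self.months)) or \
                set(self.months) - set(range(1, 13)):
            raise ValueError("months must be distinct calendar months")


@dataclass
class Scene:
    config: SceneConfig
    spec: GridSpec
    dem: Grid
    slope: Grid
    land_use: Grid
    habitat: Grid
    soil: Grid
    ndvi_monthly: dict[int, Grid]
    stations: list[StationSeries]
    features: list[MineFeature]
    rivers: list
    lakes: list
    protection_areas: list = field(default_factory=list)

    @property
    def ndvi_annual(self) -> Grid:
        vals = np.mean([g.values for g in self.ndvi_monthly.values()], axis=0)
        return Grid(self.spec, vals)


@dataclass
class ScoredSample:
    x: float
    y: float
    region: str                 # "mining" | "non_mining"
    score: float
    source: str                 # "standard_ei" | "field_survey_synthetic"

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")
        if self.region not in ("mining", "non_mining"):
            raise ValueError(f"unknown region {self.region!r}")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _quantile_classes(score: np.ndarray, mixture: Mapping[int, float],
                      order: Sequence[int]) -> np.ndarray:
    """Carve a continuous field into contiguous classes by quantiles."""
    probs = np.cumsum([mixture.get(c, 0.0) for c in order])[:-1]
    cuts = np.quantile(score, probs)
    idx = np.searchsorted(cuts, score, side="right")
    codes = np.asarray(order)[idx]
    return codes.astype(np.int64)


def make_scene(cfg: SceneConfig = SceneConfig()) -> Scene:
    """Generate the full synthetic study scene for one config."""
    rng = np.random.default_rng(cfg.seed)
    spec = GridSpec(cfg.n_rows, cfg.n_cols, cfg.cell_size)
    shape = spec.shape
    xmin, ymin, xmax, ymax = spec.bounds

    # terrain: smooth correlated random field, slope from its gradient
    relief = _smooth_field(rng, shape, sigma=12.0)
    dem_vals = 400.0 + 220.0 * relief
    dem = Grid(spec, dem_vals)
    gy, gx = np.gradient(dem_vals, cfg.cell_size)
    slope = Grid(spec, np.degrees(np.arctan(np.hypot(gx, gy))))

    # land use: terrain-correlated smooth field cut at mixture quantiles
    lu_field = 0.6 * relief + 0.8 * _smooth_field(rng, shape, sigma=9.0)
    land_use = Grid(spec, _quantile_classes(lu_field, cfg.landuse_mixture,
                                            _LANDUSE_ORDER),
                    kind="categorical")

    # habitat subtypes within each class
    sub_field = _smooth_field(rng, shape, sigma=6.0)
    habitat_vals = np.zeros(shape, dtype=np.int64)
    for cls, mix in _HABITAT_MIX.items():
        m = land_use.values == cls
        if not m.any():
            continue
        order = sorted(mix)
        habitat_vals[m] = _quantile_classes(sub_field[m], mix, order)
    habitat = Grid(spec, habitat_vals, kind="categorical")

    # soils: four classes in smooth patches
    soil_field = _smooth_field(rng, shape, sigma=14.0)
    soil_vals = _quantile_classes(
        soil_field, {SOIL_NEW: 0.25, SOIL_FLUVO_AQUIC: 0.25,
                     SOIL_CINNAMON: 0.25, SOIL_LOESS: 0.25},
        (SOIL_NEW, SOIL_FLUVO_AQUIC, SOIL_CINNAMON, SOIL_LOESS))

    # mine sites: clustered features of all seven classes
    margin = min(1500.0, 0.2 * min(xmax - xmin, ymax - ymin))
    features: list[MineFeature] = []
    site_centres = np.column_stack([
        rng.uniform(xmin + margin, xmax - margin, cfg.n_mine_sites),
        rng.uniform(ymin + margin, ymax - margin, cfg.n_mine_sites)])
    n_metal = int(round(cfg.metal_fraction * cfg.n_mine_sites))
    for i, (sx, sy) in enumerate(site_centres):
        mineral = "metal" if i < n_metal else "non_metal"
        method = "open_pit" if (i % 2 == 0) else "underground"

        def _rect(dx, dy, hw, hh):
            return shapely.box(sx + dx - hw, sy + dy - hh,
                               sx + dx + hw, sy + dy + hh)

        jit = lambda s: float(rng.uniform(-s, s))
        features.append(MineFeature(_rect(0, 0, 80 + jit(20), 60 + jit(15)),
                                    "stope", mineral, method))
        if method == "open_pit":
            features.append(MineFeature(
                _rect(220 + jit(40), jit(60), 70, 55), "open_pit",
                mineral, method))
        features.append(MineFeature(
            _rect(-250 + jit(40), 150 + jit(40), 45, 40),
            "concentrator_plant", mineral, method))
        features.append(MineFeature(
            _rect(120 + jit(30), -200 + jit(30), 40, 35), "ore_pile",
            mineral, method))
        if mineral == "non_metal":
            features.append(MineFeature(
                _rect(-150 + jit(30), -220 + jit(30), 45, 40), "coal_pile",
                mineral, method))
            features.append(MineFeature(
                _rect(280 + jit(40), 200 + jit(40), 55, 45), "dumping_site",
                mineral, method))
        else:
            features.append(MineFeature(
                _rect(250 + jit(40), 230 + jit(40), 70, 55), "tailings_pond",
                mineral, method))

    # highly erodible soils accumulate near the workings
    X, Y = spec.cell_centres()
    for i, (sx, sy) in enumerate(site_centres):
        near = np.hypot(X - sx, Y - sy) <= 450.0
        soil_vals[near] = SOIL_CINNAMON if i % 2 == 0 else SOIL_LOESS
    soil = Grid(spec, soil_vals, kind="categorical")

    # rivers: one meandering west-east trunk plus a tributary
    xs = np.linspace(xmin, xmax, 24)
    yc = (ymin + ymax) / 2
    wiggle = np.cumsum(rng.normal(0, 0.35, len(xs)))
    wiggle -= np.linspace(wiggle[0], wiggle[-1], len(xs))
    ys = yc + 0.18 * (ymax - ymin) * wiggle / max(np.abs(wiggle).max(), 1.0)
    trunk = LineString(np.column_stack([xs, ys]))
    t_idx = len(xs) // 3
    trib = LineString([(xs[t_idx], ymax - margin),
                       (xs[t_idx] + 400.0, (ys[t_idx] + ymax - margin) / 2),
                       (xs[t_idx], ys[t_idx])])
    rivers = [trunk, trib]
    lakes = [Point(xs[2 * len(xs) // 3], ys[2 * len(xs) // 3]).buffer(250.0),
             Point(xs[5], ys[5]).buffer(180.0)]

    # monthly NDVI: class baseline, seasonal cycle, spatial noise, and
    # vegetation suppression near the workings
    ndvi_noise = 0.08 * _smooth_field(rng, shape, sigma=5.0)
    base = np.zeros(shape)
    for cls, v in _NDVI_BASE.items():
        base[land_use.values == cls] = v
    suppress = np.ones(shape)
    for sx, sy in site_centres:
        suppress[np.hypot(X - sx, Y - sy) <= 350.0] = 0.6
    ndvi_monthly: dict[int, Grid] = {}
    for m in cfg.months:
        seasonal = 0.75 + 0.25 * np.sin(2 * np.pi * (m - 4) / 12.0)
        vals = np.clip(base * seasonal * suppress + ndvi_noise, -0.25, 0.92)
        ndvi_monthly[m] = Grid(spec, vals)

    # station meteorology: seasonal cycles plus station-level gradients
    stations: list[StationSeries] = []
    st_xy = np.column_stack([
        rng.uniform(xmin + 500, xmax - 500, cfg.n_stations),
        rng.uniform(ymin + 500, ymax - 500, cfg.n_stations)])
    for i, (sx, sy) in enumerate(st_xy):
        u = (sx - xmin) / (xmax - xmin)      # west-east gradient
        v = (sy - ymin) / (ymax - ymin)      # south-north gradient
        months = list(cfg.months)
        rain, temp, sol, aqi, wind = [], [], [], [], []
        annual_rain = cfg.annual_rainfall_mm * (1.0 + 0.15 * (v - 0.5)
                                                + float(rng.normal(0, 0.03)))
        for m in months:
            share = _RAIN_SHARE.get(m, _RAIN_REST)
            rain.append(annual_rain * share * (1 + float(rng.normal(0, 0.05))))
            temp.append(cfg.mean_temperature_c
                        - 11.0 * np.cos(2 * np.pi * (m - 7) / 12.0)
                        - 2.0 * (v - 0.5) + float(rng.normal(0, 0.4)))
            sol.append(max(480.0 - 240.0 * np.cos(2 * np.pi * (m - 6.5) / 12.0)
                           + 30.0 * (u - 0.5) + float(rng.normal(0, 12.0)),
                           10.0))
            aqi.append(max(95.0 + 45.0 * np.cos(2 * np.pi * (m - 1) / 12.0)
                           + 15.0 * (u - 0.5) + float(rng.normal(0, 6.0)),
                           10.0))
            wind.append(max(2.6 + 0.8 * np.sin(2 * np.pi * (m - 3) / 12.0)
                            + 0.5 * (v - 0.5) + float(rng.normal(0, 0.2)),
                            0.5))
        stations.append(StationSeries(
            station_id=f"S{i:02d}", x=float(sx), y=float(sy), months=months,
            rainfall=rain, temperature=temp, solar_radiation=sol, aqi=aqi,
            wind_speed=wind))

    return Scene(config=cfg, spec=spec, dem=dem, slope=slope,
                 land_use=land_use, habitat=habitat, soil=soil,
                 ndvi_monthly=ndvi_monthly, stations=stations,
                 features=features, rivers=rivers, lakes=lakes)


def make_seasons(stations: Sequence[StationSeries]) -> dict[str, pd.DataFrame]:
    """Seasonal station aggregates: means of temperature/AQI/wind, sums of
    rainfall/solar radiation, for the four March-first seasons."""
    months_present = set(stations[0].months) if stations else set()
    if months_present != set(range(1, 13)):
        raise ValueError("stations must cover all 12 months")
    out = {}
    for season, months in SEASON_MONTHS.items():
        rows = []
        for s in stations:
            rows.append({
                "station_id": s.station_id, "x": s.x, "y": s.y,
                "rainfall": sum(s.month_value("rainfall", m) for m in months),
                "solar_radiation": sum(s.month_value("solar_radiation", m)
                                       for m in months),
                "temperature": float(np.mean(
                    [s.month_value("temperature", m) for m in months])),
                "aqi": float(np.mean(
                    [s.month_value("aqi", m) for m in months])),
                "wind_speed": float(np.mean(
                    [s.month_value("wind_speed", m) for m in months])),
            })
        out[season] = pd.DataFrame(rows)
    return out


def _proportional_counts(sizes: Mapping[str, int], total: int) -> dict[str, int]:
    """Largest-remainder allocation, at least one per non-empty stratum."""
    keys = sorted(k for k, n in sizes.items() if n > 0)
    weights = np.array([sizes[k] for k in keys], dtype=float)
    raw = weights / weights.sum() * total
    counts = np.maximum(np.floor(raw).astype(int), 1)
    while counts.sum() > total:
        counts[np.argmax(counts)] -= 1
    rema = raw - np.floor(raw)
    order = np.argsort(-rema)
    i = 0
    while counts.sum() < total:
        counts[order[i % len(keys)]] += 1
        i += 1
    return dict(zip(keys, counts.tolist()))


def make_samples(scene: Scene, n_non_mining: int = 700, n_mining: int = 100,
                 seed: int = 0, noise_sd: float | None = None,
                 season: str = "annual") -> list[ScoredSample]:
    """Scored sample points mirroring the study's sampling design.

    Non-mining points are scored by the standard EI pipeline for the given
    season; mining points are scored by the documented ground-truth function
    (EI minus equal 0.2 penalties on the four mine-impact layers) plus
    Gaussian noise of sd ``noise_sd`` (default: the scene config's), clipped
    to [0, 1].  Mining sampling is stratified proportionally by mine feature
    class, so every class present in the scene is sampled.
    """
    from .assessment import compute_layers  # local import; no cycle at module load

    if noise_sd is None:
        noise_sd = scene.config.noise_sd
    rng = np.random.default_rng(seed)
    layers = compute_layers(scene, season=season)
    spec = scene.spec
    mask = layers.mask
    ei_vals = layers.ei.values
    penalty = 0.2 * (layers.mine["air_pollution"].values
                     + layers.mine["solid_waste"].values
                     + layers.mine["geologic_hazard"].values
                     + layers.mine["soil_pollution"].values)
    truth_mining = np.clip(ei_vals - penalty, 0.0, 1.0)

    X, Y = spec.cell_centres()
    samples: list[ScoredSample] = []

    nm_idx = np.flatnonzero(mask.non_mining.ravel())
    if nm_idx.size == 0:
        raise ValueError("non-mining region is empty")
    chosen = rng.choice(nm_idx, size=min(n_non_mining, nm_idx.size),
                        replace=False)
    for flat in chosen:
        samples.append(ScoredSample(
            x=float(X.ravel()[flat]), y=float(Y.ravel()[flat]),
            region="non_mining",
            score=float(np.clip(ei_vals.ravel()[flat], 0, 1)),
            source="standard_ei"))

    if not mask.mining.any():
        raise ValueError("mining region is empty")
    by_class: dict[str, list[int]] = {}
    for i, f in enumerate(scene.features):
        by_class.setdefault(f.feature_class, []).append(i)
    counts = _proportional_counts({k: len(v) for k, v in by_class.items()},
                                  n_mining)
    from .grids import distance_to_features
    mining_flat = mask.mining.ravel()
    cand_cache: dict[tuple[int, float], np.ndarray] = {}

    def _candidates(fi: int, radius: float) -> np.ndarray:
        key = (fi, radius)
        if key not in cand_cache:
            d = distance_to_features([scene.features[fi]], spec).values.ravel()
            cand = np.flatnonzero((d <= radius) & mining_flat)
            if cand.size == 0:  # feature clipped to the scene edge
                cand = np.flatnonzero((d <= 1000.0) & mining_flat)
            cand_cache[key] = cand
        return cand_cache[key]

    # Field crews score the mine element itself and its surroundings, so
    # half of each class's allocation falls on/beside the feature (<=100 m,
    # which keeps the small-support impact layers identifiable) and half
    # anywhere in its 1000 m neighbourhood.
    for cls in sorted(counts):
        feats = by_class[cls]
        for j in range(counts[cls]):
            fi = feats[int(rng.integers(len(feats)))]
            radius = 100.0 if j % 2 == 0 else 1000.0
            cand = _candidates(fi, radius)
            flat = int(rng.choice(cand))
            noisy = truth_mining.ravel()[flat] + rng.normal(0.0, noise_sd) \
                if noise_sd > 0 else truth_mining.ravel()[flat]
            samples.append(ScoredSample(
                x=float(X.ravel()[flat]), y=float(Y.ravel()[flat]),
                region="mining", score=float(np.clip(noisy, 0, 1)),
                source="field_survey_synthetic"))
    return samples


def write_scene(scene: Scene, out_dir: str | Path) -> None:
    """Write the scene in the pipeline's file formats (TIFF/GeoJSON/CSV)."""
    from . import io as msio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    msio.write_raster(scene.dem, out / "dem.tif")
    msio.write_raster(scene.slope, out / "slope.tif")
    msio.write_raster(scene.land_use, out / "land_use.tif")
    msio.write_raster(scene.habitat, out / "habitat.tif")
    msio.write_raster(scene.soil, out / "soil.tif")
    for m, g in scene.ndvi_monthly.items():
        msio.write_raster(g, out / f"ndvi_{m:02d}.tif")
    msio.write_features(scene.features, out / "mine_features.geojson")
    msio.write_generic_geojson(scene.rivers, out / "rivers.geojson")
    msio.write_generic_geojson(scene.lakes, out / "lakes.geojson")
    msio.write_stations(scene.stations, out / "stations.csv")
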