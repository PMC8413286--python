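"""Per-region score models and the fused assessment map.

The improved evaluation system stacks nine aligned factor layers — the five
standard sub-indices plus the four mine-impact layers — samples them at
scored points, trains one score model per region (SVM regression, a CART
regression tree, and a C5.0-like stand-in), selects the best model per
region on held-out points, and composes the two regional predictions into a
single assessment map that is then classified into five levels.

The modelling surface follows the Model / Results convention:
``EcoAssessment(stack, samples, mask, land_use).fit(seed)`` returns an
:class:`EcoAssessmentResults` carrying the fused map, the per-region model
selection with its held-out accuracy, the per-land-use accuracy table and
the map-vs-layer Pearson correlations, with a ``summary()`` text table.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from . import casa, indices, kriging, minefactors
from .constants import CLASS_NAMES, LANDUSE_NAMES, SEASON_MONTHS
from .grids import Grid, minmax_normalize
from .indices import classify_five
from .minefactors import RegionMask

__all__ = ["LAYER_ORDER", "FeatureStack", "SceneLayers", "compute_layers",
           "build_stack", "extract_training", "train_model", "ScoreModel",
           "AssessmentMap", "select_and_fuse", "accuracy_table",
           "pearson_table", "EcoAssessment", "EcoAssessmentResults",
           "run_pipeline", "PipelineResult"]

LAYER_ORDER = (
    "biological_abundance", "vegetation_coverage", "river_density",
    "land_stress", "pollution_loading",
    "air_pollution", "solid_waste", "geologic_hazard", "soil_pollution",
)
MODEL_TYPES = ("svm", "cart", "c50")


@dataclass
class FeatureStack:
    """Ordered, aligned, normalized factor layers with a provenance hash."""

    layers: dict[str, Grid]

    def __post_init__(self) -> None:
        missing = [n for n in LAYER_ORDER if n not in self.layers]
        if missing:
            raise ValueError(f"missing stack layer(s): {missing}")
        spec = self.spec
        for name in LAYER_ORDER:
            g = self.layers[name]
            if g.spec != spec:
                raise ValueError(f"layer {name!r} is misaligned")
            v = np.asarray(g.values, float)[g.valid]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise ValueError(f"layer {name!r} not normalized to [0, 1]")

    @property
    def spec(self):
        return self.layers[LAYER_ORDER[0]].spec

    @property
    def provenance_hash(self) -> str:
        h = hashlib.sha256()
        for name in LAYER_ORDER:
            h.update(name.encode())
            h.update(np.ascontiguousarray(
                self.layers[name].values, dtype=np.float64).tobytes())
        return h.hexdigest()

    def as_matrix(self) -> np.ndarray:
        """(n_cells, 9) design matrix in layer order, row-major cells."""
        return np.column_stack(
            [np.asarray(self.layers[n].values, float).ravel()
             for n in LAYER_ORDER])


def build_stack(index_layers: Mapping[str, Grid],
                mine_layers: Mapping[str, Grid]) -> FeatureStack:
    return FeatureStack({**dict(index_layers), **dict(mine_layers)})


# ---------------------------------------------------------------------------
# scene -> layers
# ---------------------------------------------------------------------------

@dataclass
class SceneLayers:
    """Everything the models consume for one season of one scene."""

    season: str
    indices: dict[str, Grid]
    mine: dict[str, Grid]
    ei: Grid
    mask: RegionMask
    stack: FeatureStack


def _krige_station_variable(scene, values_by_station, params=None) -> Grid:
    pts = [(s.x, s.y, v) for s, v in zip(scene.stations, values_by_station)]
    return kriging.krige_spherical(pts, scene.spec, params=params)


def compute_layers(scene, season: str = "annual",
                   _static_cache: dict | None = None) -> SceneLayers:
    """Compute the five standard indices, the four mine factors, the EI
    composite, the region mask and the nine-layer stack for one season.

    ``season`` is one of spring/summer/autumn/winter or "annual" (all 12
    months).  Land-bound layers (vegetation coverage, river density, land
    stress, habitat quality, elevation, the mine factors and the region
    mask) are season-invariant; only the meteorology-driven layers vary.
    An optional cache dict lets multi-season runs share the static layers.
    """
    if season == "annual":
        months = list(scene.config.months)
    elif season in SEASON_MONTHS:
        months = [m for m in SEASON_MONTHS[season] if m in scene.config.months]
        if not months:
            raise ValueError(f"no configured months in season {season!r}")
    else:
        raise ValueError(f"unknown season {season!r}")

    cache = _static_cache if _static_cache is not None else {}
    if "static" not in cache:
        ndvi_annual = scene.ndvi_annual
        veg = indices.vegetation_coverage_index(ndvi_annual)
        hq = indices.habitat_quality(scene.land_use, scene.habitat)
        f_alt = minmax_normalize(scene.dem)
        river = indices.river_density_index(
            scene.rivers, scene.lakes, scene.config.resources_amount,
            scene.spec)
        erosion = indices.classify_erosion(scene.land_use, scene.soil, veg)
        stress = indices.land_stress_index(erosion)
        wind_annual = [float(np.mean(s.wind_speed)) for s in scene.stations]
        wind = _krige_station_variable(scene, wind_annual)
        wind = Grid(scene.spec, np.maximum(wind.values, 0.1))
        air = minefactors.air_pollution_range(scene.features, wind,
                                              scene.spec)
        solid = minefactors.solid_waste_area(scene.features, scene.spec)
        hazard = minefactors.geologic_hazard_range(scene.features, scene.spec)
        nm, mt = minefactors.soil_pollution_buffer(scene.features, scene.spec)
        soil_combined = Grid(scene.spec, np.maximum(nm.values, mt.values))
        mask = minefactors.region_split(scene.features,
                                        scene.protection_areas, scene.spec)
        cache["static"] = {
            "vegetation_coverage": veg, "habitat_quality": hq,
            "f_alt": f_alt, "river_density": river, "land_stress": stress,
            "air_pollution": air, "solid_waste": solid,
            "geologic_hazard": hazard, "soil_pollution": soil_combined,
            "soil_pollution_non_metal": nm, "soil_pollution_metal": mt,
            "mask": mask,
        }
    st = cache["static"]

    # seasonal meteorology
    rain = _krige_station_variable(
        scene, [sum(s.month_value("rainfall", m) for m in months)
                for s in scene.stations])
    temp = _krige_station_variable(
        scene, [float(np.mean([s.month_value("temperature", m)
                               for m in months])) for s in scene.stations])
    aqi = _krige_station_variable(
        scene, [float(np.mean([s.month_value("aqi", m) for m in months]))
                for s in scene.stations])
    aqi = Grid(scene.spec, np.maximum(aqi.values, 0.0))

    monthly_npp = []
    for m in months:
        sol = _krige_station_variable(
            scene, [s.month_value("solar_radiation", m)
                    for s in scene.stations])
        sol = Grid(scene.spec, np.maximum(sol.values, 0.0))
        monthly_npp.append(casa.npp_month(
            sol, scene.ndvi_monthly[m], scene.land_use,
            habitat=scene.habitat))
    npp_norm = casa.npp_mean_normalized(monthly_npp)

    bi = indices.biodiversity_index(indices.BiFactors(
        npp_mean=npp_norm, f_pre=minmax_normalize(rain),
        f_tem=minmax_normalize(temp), f_alt=st["f_alt"]))
    bio = indices.biological_abundance_index(bi, st["habitat_quality"])
    pollution = indices.pollution_loading_index(aqi)

    idx_layers = {
        "biological_abundance": bio,
        "vegetation_coverage": st["vegetation_coverage"],
        "river_density": st["river_density"],
        "land_stress": st["land_stress"],
        "pollution_loading": pollution,
    }
    mine_layers = {k: st[k] for k in ("air_pollution", "solid_waste",
                                      "geologic_hazard", "soil_pollution")}
    ei_grid = indices.ei(bio, st["vegetation_coverage"], st["river_density"],
                         st["land_stress"], pollution)
    return SceneLayers(season=season, indices=idx_layers, mine=mine_layers,
                       ei=ei_grid, mask=st["mask"],
                       stack=build_stack(idx_layers, mine_layers))


# ---------------------------------------------------------------------------
# training data and models
# ---------------------------------------------------------------------------

def extract_training(stack: FeatureStack, samples: Sequence) -> tuple[
        np.ndarray, np.ndarray, np.ndarray]:
    """One row per sample: the nine layer values at the sample's cell.

    Returns (X, y, regions).  Rows hitting nodata in any layer are dropped
    (count reported via warning); duplicate locations yield duplicate rows.
    """
    spec = stack.spec
    rows, targets, regions = [], [], []
    n_dropped = 0
    grids = [stack.layers[n] for n in LAYER_ORDER]
    for s in samples:
        r, c = spec.index_of(s.x, s.y)
        vals = [float(np.asarray(g.values, float)[r, c]) for g in grids]
        if any(not g.valid[r, c] for g in grids) or \
                any(np.isnan(v) for v in vals):
            n_dropped += 1
            continue
        rows.append(vals)
        targets.append(s.score)
        regions.append(s.region)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} sample(s) hitting nodata",
                      stacklevel=2)
    if not rows:
        raise ValueError("no usable training rows (all hit nodata)")
    return (np.asarray(rows), np.asarray(targets),
            np.asarray(regions, dtype=object))


class _ConstantModel:
    def __init__(self, value: float):
        self.value = float(value)

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value)


class _ClassMidpointTree:
    """C5.0-like stand-in: an information-gain (entropy) decision tree on
    the 5-level classes, predicting each class's score midpoint.  The
    proprietary C5.0 algorithm itself is not reproduced; this preserves its
    comparison role as an entropy-based tree."""

    def __init__(self, seed: int = 0, max_depth: int = 14,
                 min_samples_leaf: int = 1):
        self.tree = DecisionTreeClassifier(
            criterion="entropy", max_depth=max_depth,
            min_samples_leaf=min_samples_leaf, random_state=seed)

    def fit(self, X, y):
        self.tree.fit(X, classify_five(np.asarray(y)))
        return self

    def predict(self, X):
        cls = self.tree.predict(X)
        return (cls - 0.5) * 0.2  # midpoint of each 0.2-wide level


@dataclass
class ScoreModel:
    """A fitted per-region score model; predictions are clipped to [0, 1]."""

    model_type: str
    estimator: object
    region: str = ""
    n_train: int = 0
    seed: int = 0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.estimator.predict(np.asarray(X)), 0.0, 1.0)


# default hyperparameter grids searched by internal cross-validation
SVM_GRID = tuple(
    [{"kernel": "linear", "C": C, "epsilon": e}
     for C in (0.3, 1.0, 10.0)
     for e in (0.003, 0.05)]
    + [{"kernel": "rbf", "C": C, "epsilon": e, "gamma": g}
       for C in (1.0, 10.0, 100.0)
       for e in (0.003, 0.05)
       for g in (0.01, 0.05)])
TREE_GRID = tuple({"max_depth": d, "min_samples_leaf": l}
                  for d in (6, 10, 14) for l in (1, 3, 8))


def _make_estimator(model_type: str, hp: Mapping, seed: int):
    if model_type == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svr", SVR(kernel=hp.get("kernel", "rbf"),
                        C=hp.get("C", 100.0),
                        epsilon=hp.get("epsilon", 0.003),
                        gamma=hp.get("gamma", 0.02)))])
    if model_type == "cart":
        return DecisionTreeRegressor(
            max_depth=hp.get("max_depth", 14),
            min_samples_leaf=hp.get("min_samples_leaf", 1),
            random_state=seed)
    if model_type == "c50":
        return _ClassMidpointTree(seed=seed,
                                  max_depth=hp.get("max_depth", 14),
                                  min_samples_leaf=hp.get("min_samples_leaf", 1))
    raise ValueError(f"unknown model type {model_type!r}")


def _capacity_key(model_type: str, hp: Mapping) -> tuple:
    """Sort key ordering hyperparameters from most to least regularised."""
    if model_type == "svm":
        return (0 if hp.get("kernel", "rbf") == "linear" else 1,
                hp["C"], hp.get("gamma", 0.0), -hp["epsilon"])
    return (hp["max_depth"], -hp["min_samples_leaf"])


def _cv_select(model_type: str, X: np.ndarray, y: np.ndarray, seed: int,
               n_folds: int = 4, n_repeats: int = 3) -> Mapping:
    """Pick hyperparameters by seeded repeated k-fold CV squared error.

    Applies the one-standard-error rule: among configurations whose CV
    error is within one standard error of the minimum, the most
    regularised one wins.  This adapts model capacity to the (unknown)
    noise level of the scores while guarding against fold-level noise in
    the CV estimate itself; everything is seeded, so the choice is
    deterministic."""
    grid = SVM_GRID if model_type == "svm" else TREE_GRID
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        order = rng.permutation(len(y))
        folds = np.array_split(order, n_folds)
        for i in range(n_folds):
            test = folds[i]
            train = np.concatenate([folds[j] for j in range(n_folds)
                                    if j != i])
            splits.append((train, test))
    fold_mse = np.empty((len(grid), len(splits)))
    for gi, hp in enumerate(grid):
        for si, (train, test) in enumerate(splits):
            est = _make_estimator(model_type, hp, seed).fit(X[train], y[train])
            pred = np.clip(est.predict(X[test]), 0.0, 1.0)
            fold_mse[gi, si] = np.mean((pred - y[test]) ** 2)
    mean_mse = fold_mse.mean(axis=1)
    best_gi = int(np.argmin(mean_mse))
    se_best = float(fold_mse[best_gi].std(ddof=1) / np.sqrt(len(splits)))
    admissible = [grid[gi] for gi in range(len(grid))
                  if mean_mse[gi] <= mean_mse[best_gi] + se_best]
    return min(admissible, key=lambda hp: _capacity_key(model_type, hp))


def train_model(X: np.ndarray, y: np.ndarray, model_type: str,
                seed: int = 0, region: str = "",
                hyperparams: Mapping | None = None) -> ScoreModel:
    """Fit one score model.

    When no hyperparameters are supplied they are chosen by seeded repeated
    4-fold cross-validation with the one-standard-error rule over a small
    grid (linear- and RBF-kernel SVR on standardized features; depth/leaf-
    capped trees), so the capacity adapts to however noisy the reference
    scores are.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if len(X) < 20:
        raise ValueError("need at least 20 training rows")
    if np.allclose(y, y[0]):
        warnings.warn("constant training targets; fitting a constant "
                      "predictor", stacklevel=2)
        est = _ConstantModel(y[0]).fit(X, y)
    else:
        hp = dict(hyperparams) if hyperparams else _cv_select(
            model_type, X, y, seed)
        est = _make_estimator(model_type, hp, seed).fit(X, y)
    return ScoreModel(model_type=model_type, estimator=est, region=region,
                      n_train=len(X), seed=seed)


# ---------------------------------------------------------------------------
# fusion, tables
# ---------------------------------------------------------------------------

@dataclass
class AssessmentMap:
    score: Grid
    classes: Grid


def class_agreement(pred_scores: np.ndarray, ref_scores: np.ndarray) -> float:
    """Fraction of points whose 5-level class matches the reference's."""
    return float(np.mean(classify_five(np.asarray(pred_scores))
                         == classify_five(np.asarray(ref_scores))))


def select_and_fuse(models: Mapping[str, Mapping[str, ScoreModel]],
                    stack: FeatureStack, mask: RegionMask,
                    validation: Mapping[str, tuple[np.ndarray, np.ndarray]],
                    ) -> tuple[AssessmentMap, dict[str, dict]]:
    """Pick the best model per region on held-out points and compose the map.

    ``models[region][model_type]`` are fitted models;
    ``validation[region] = (X_val, y_val)``.  Returns the fused
    :class:`AssessmentMap` and a per-region selection record.
    """
    spec = stack.spec
    X_full = stack.as_matrix()
    fused = np.zeros(spec.n_rows * spec.n_cols)
    selection: dict[str, dict] = {}
    region_masks = {"mining": mask.mining.ravel(),
                    "non_mining": mask.non_mining.ravel()}
    for region, per_type in models.items():
        Xv, yv = validation[region]
        if len(yv) == 0:
            raise ValueError(f"empty validation set for region {region!r}")
        scores = {}
        for mtype, model in per_type.items():
            pred = model.predict(Xv)
            scores[mtype] = {
                "accuracy_pct": 100.0 * class_agreement(pred, yv),
                "rmse": float(np.sqrt(np.mean((pred - yv) ** 2))),
            }
        best = max(sorted(scores), key=lambda t: scores[t]["accuracy_pct"])
        selection[region] = {"selected": best, "candidates": scores,
                             "n_validation": int(len(yv)),
                             **scores[best]}
        m = region_masks[region]
        if m.any():
            fused[m] = per_type[best].predict(X_full[m])
    score = Grid(spec, fused.reshape(spec.shape))
    return AssessmentMap(score=score, classes=classify_five(score)), selection


def accuracy_table(amap: AssessmentMap, samples: Sequence,
                   land_use: Grid, mask: RegionMask) -> pd.DataFrame:
    """Five-level class agreement of the map against reference scores at
    validation points, per region and land-use type plus pooled totals.

    Land-use classes with no validation points are absent from the table,
    not reported as 0 %.
    """
    spec = amap.score.spec
    rows = []
    recs = []
    for s in samples:
        r, c = spec.index_of(s.x, s.y)
        recs.append((s.region, int(land_use.values[r, c]),
                     float(amap.score.values[r, c]), s.score))
    df = pd.DataFrame(recs, columns=["region", "land_use_code", "pred", "ref"])
    df["match"] = (classify_five(df["pred"].to_numpy())
                   == classify_five(df["ref"].to_numpy()))
    for (region, code), sub in df.groupby(["region", "land_use_code"]):
        rows.append({"region": region,
                     "land_use": LANDUSE_NAMES.get(code, str(code)),
                     "n": len(sub),
                     "accuracy_pct": 100.0 * sub["match"].mean()})
    for region, sub in df.groupby("region"):
        rows.append({"region": region, "land_use": "all", "n": len(sub),
                     "accuracy_pct": 100.0 * sub["match"].mean()})
    return pd.DataFrame(rows)


def pearson_table(score: Grid, stack: FeatureStack) -> pd.DataFrame:
    """Pearson r between the score map and each stack layer over the
    common valid support; zero-variance layers report NaN."""
    valid = score.valid
    rows = []
    for name in LAYER_ORDER:
        g = stack.layers[name]
        m = valid & g.valid
        if m.sum() < 3:
            raise ValueError("need at least 3 common valid cells")
        a = np.asarray(score.values, float)[m]
        b = np.asarray(g.values, float)[m]
        if np.ptp(b) == 0 or np.ptp(a) == 0:
            r = float("nan")
        else:
            r = float(stats.pearsonr(a, b).statistic)
        rows.append({"layer": name, "pearson_r": r})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class EcoAssessment:
    """Per-region eco-environment score model over a nine-layer stack.

    Parameters
    ----------
    stack : FeatureStack
        The five standard indices plus four mine-impact layers.
    samples : sequence of ScoredSample
        Scored points in both regions; split internally into training and
        held-out validation sets.
    mask : RegionMask
        Mining / non-mining partition of the scene.
    land_use : Grid
        Categorical land use, used for the per-type accuracy table.
    """

    def __init__(self, stack: FeatureStack, samples: Sequence,
                 mask: RegionMask, land_use: Grid,
                 model_types: Sequence[str] = MODEL_TYPES,
                 holdout_frac: float = 0.25,
                 hyperparams: Mapping | None = None):
        if not 0 < holdout_frac < 1:
            raise ValueError("holdout_frac must be in (0, 1)")
        self.stack = stack
        self.samples = list(samples)
        self.mask = mask
        self.land_use = land_use
        self.model_types = tuple(model_types)
        self.holdout_frac = holdout_frac
        self.hyperparams = hyperparams or {}

    @classmethod
    def from_scene(cls, scene, samples=None, season: str = "annual",
                   sample_seed: int = 0, **kwargs) -> "EcoAssessment":
        from .scene import make_samples
        layers = compute_layers(scene, season=season)
        if samples is None:
            samples = make_samples(scene, seed=sample_seed, season=season)
        return cls(layers.stack, samples, layers.mask,
                   scene.land_use, **kwargs)

    def fit(self, seed: int = 0) -> "EcoAssessmentResults":
        rng = np.random.default_rng(seed)
        X, y, regions = extract_training(self.stack, self.samples)
        models: dict[str, dict[str, ScoreModel]] = {}
        validation: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        val_samples = []
        sample_arr = np.asarray(
            [s for s in self.samples], dtype=object)
        for region in ("non_mining", "mining"):
            idx = np.flatnonzero(regions == region)
            if idx.size == 0:
                continue
            perm = rng.permutation(idx)
            n_hold = max(int(round(self.holdout_frac * idx.size)), 1)
            hold, train = perm[:n_hold], perm[n_hold:]
            validation[region] = (X[hold], y[hold])
            val_samples.extend(sample_arr[hold].tolist())
            models[region] = {
                mtype: train_model(X[train], y[train], mtype, seed=seed,
                                   region=region,
                                   hyperparams=self.hyperparams.get(mtype))
                for mtype in self.model_types}
        amap, selection = select_and_fuse(models, self.stack, self.mask,
                                          validation)
        acc = accuracy_table(amap, val_samples, self.land_use, self.mask)
        pear = pearson_table(amap.score, self.stack)
        return EcoAssessmentResults(
            model=self, map=amap, models=models, selection=selection,
            accuracy=acc, pearson=pear, seed=seed,
            validation_samples=val_samples)


@dataclass
class EcoAssessmentResults:
    """Fitted assessment: fused map, per-region selection, report tables."""

    model: EcoAssessment
    map: AssessmentMap
    models: dict[str, dict[str, ScoreModel]]
    selection: dict[str, dict]
    accuracy: pd.DataFrame
    pearson: pd.DataFrame
    seed: int
    validation_samples: list = field(default_factory=list)

    @property
    def score(self) -> Grid:
        return self.map.score

    @property
    def classes(self) -> Grid:
        return self.map.classes

    def class_share(self) -> dict[str, float]:
        """Fraction of scene cells in each of the five levels."""
        vals = self.map.classes.values
        return {CLASS_NAMES[k]: float(np.mean(vals == k))
                for k in CLASS_NAMES}

    def summary(self) -> str:
        lines = ["Eco-environment assessment results",
                 "=" * 50,
                 f"stack hash    : {self.model.stack.provenance_hash[:16]}…",
                 f"fit seed      : {self.seed}",
                 ""]
        for region, sel in self.selection.items():
            lines.append(
                f"{region:>11s}: {sel['selected'].upper():4s} "
                f"accuracy {sel['accuracy_pct']:.2f} %  "
                f"rmse {sel['rmse']:.4f}  "
                f"(n_val={sel['n_validation']})")
            for mtype, sc in sorted(sel["candidates"].items()):
                lines.append(f"{'':>13s}{mtype:5s} "
                             f"{sc['accuracy_pct']:6.2f} %  "
                             f"rmse {sc['rmse']:.4f}")
        lines.append("")
        lines.append("Pearson r (map vs layer):")
        for _, row in self.pearson.iterrows():
            lines.append(f"  {row['layer']:<22s} {row['pearson_r']:+.3f}")
        lines.append("")
        lines.append("Class shares:")
        for name, frac in self.class_share().items():
            lines.append(f"  {name:<10s} {100 * frac:5.1f} %")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    results: dict[str, EcoAssessmentResults]
    accuracy: pd.DataFrame     # all seasons stacked
    pearson: pd.DataFrame      # layer x season
    provenance: dict


def run_pipeline(scene, seasons: Sequence[str] | str = "all",
                 seed: int = 0, out_dir: str | Path | None = None,
                 n_non_mining: int = 700, n_mining: int = 100,
                 noise_sd: float | None = None) -> PipelineResult:
    """Seasonal end-to-end run: krige, compute layers, train, fuse, report.

    For every requested season the stack is rebuilt from that season's
    meteorology (land-bound layers are shared), scored samples are drawn
    with the study's 700 + 100 design, the per-region models are trained
    and selected on held-out points, and the fused map plus report tables
    are produced (and written under ``out_dir`` when given).
    """
    from .scene import make_samples
    from . import io as msio

    if seasons == "all":
        seasons = list(SEASON_MONTHS)
    elif isinstance(seasons, str):
        seasons = [seasons]
    rng = np.random.default_rng(seed)
    cache: dict = {}
    results: dict[str, EcoAssessmentResults] = {}
    acc_frames, pear_frames = [], []
    for season in seasons:
        sub_seed = int(rng.integers(2 ** 31 - 1))
        layers = compute_layers(scene, season=season, _static_cache=cache)
        samples = make_samples(scene, n_non_mining=n_non_mining,
                               n_mining=n_mining, seed=sub_seed,
                               noise_sd=noise_sd, season=season)
        model = EcoAssessment(layers.stack, samples, layers.mask,
                              scene.land_use)
        res = model.fit(seed=sub_seed)
        results[season] = res
        acc = res.accuracy.copy()
        acc.insert(0, "season", season)
        acc_frames.append(acc)
        pear = res.pearson.copy()
        pear.insert(0, "season", season)
        pear_frames.append(pear)
    accuracy = pd.concat(acc_frames, ignore_index=True)
    pearson = pd.concat(pear_frames, ignore_index=True)
    provenance = {
        "seed": seed,
        "seasons": list(seasons),
        "scene_seed": scene.config.seed,
        "n_samples": {"non_mining": n_non_mining, "mining": n_mining},
        "stack_hashes": {s: results[s].model.stack.provenance_hash
                         for s in results},
        "selection": {s: {r: results[s].selection[r]["selected"]
                          for r in results[s].selection} for s in results},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for season, res in results.items():
            msio.write_raster(res.map.score, out / f"{season}_score.tif")
            msio.write_raster(res.map.classes, out / f"{season}_class.tif")
        accuracy.to_csv(out / "accuracy.csv", index=False)
        pearson.to_csv(out / "pearson.csv", index=False)
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True))
    return PipelineResult(results=results, accuracy=accuracy,
                          pearson=pearson, provenance=provenance)
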