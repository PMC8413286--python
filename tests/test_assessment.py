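"""Feature stack, training extraction, model fit/selection, report tables."""

import numpy as np
import pandas as pd
import pytest

from minescore import make_samples
from minescore.assessment import (LAYER_ORDER, AssessmentMap, EcoAssessment,
                                  FeatureStack, accuracy_table,
                                  class_agreement, build_stack,
                                  compute_layers, extract_training,
                                  pearson_table, run_pipeline, select_and_fuse,
                                  train_model)
from minescore.grids import Grid, GridSpec
from minescore.indices import classify_five
from minescore.scene import ScoredSample


def toy_stack(rng, n=12):
    spec = GridSpec(n, n)
    return FeatureStack({name: Grid(spec, rng.random(spec.shape))
                         for name in LAYER_ORDER})


class TestFeatureStack:
    def test_missing_layer(self, rng):
        layers = {name: Grid(GridSpec(4, 4), np.zeros((4, 4)))
                  for name in LAYER_ORDER[:-1]}
        with pytest.raises(ValueError, match="soil_pollution"):
            FeatureStack(layers)

    def test_misaligned_layer(self, rng):
        layers = {name: Grid(GridSpec(4, 4), np.zeros((4, 4)))
                  for name in LAYER_ORDER}
        layers["solid_waste"] = Grid(GridSpec(5, 5), np.zeros((5, 5)))
        with pytest.raises(ValueError, match="misaligned"):
            FeatureStack(layers)

    def test_unnormalized_layer(self, rng):
        layers = {name: Grid(GridSpec(4, 4), np.zeros((4, 4)))
                  for name in LAYER_ORDER}
        layers["river_density"] = Grid(GridSpec(4, 4), np.full((4, 4), 2.0))
        with pytest.raises(ValueError, match="normalized"):
            FeatureStack(layers)

    def test_provenance_hash_tracks_content(self, rng):
        s1 = toy_stack(rng)
        h1 = s1.provenance_hash
        assert h1 == s1.provenance_hash          # stable
        s1.layers["solid_waste"].values[0, 0] += 1e-9
        assert s1.provenance_hash != h1          # content-sensitive

    def test_as_matrix_order(self, rng):
        s = toy_stack(rng, n=3)
        m = s.as_matrix()
        assert m.shape == (9, 9)
        np.testing.assert_array_equal(
            m[:, 0], s.layers[LAYER_ORDER[0]].values.ravel())
        np.testing.assert_array_equal(
            m[:, 8], s.layers[LAYER_ORDER[8]].values.ravel())

    def test_build_stack_merges(self, rng):
        s = toy_stack(rng, n=3)
        idx = {k: s.layers[k] for k in LAYER_ORDER[:5]}
        mine = {k: s.layers[k] for k in LAYER_ORDER[5:]}
        assert build_stack(idx, mine).provenance_hash == s.provenance_hash


class TestExtractTraining:
    def test_values_match_layers(self, rng):
        s = toy_stack(rng, n=6)
        spec = s.spec
        X, Y = spec.cell_centres()
        samples = [ScoredSample(x=float(X[2, 3]), y=float(Y[2, 3]),
                                region="mining", score=0.5,
                                source="field_survey_synthetic"),
                   ScoredSample(x=float(X[5, 1]), y=float(Y[5, 1]),
                                region="non_mining", score=0.7,
                                source="standard_ei")]
        Xm, y, regions = extract_training(s, samples)
        np.testing.assert_allclose(
            Xm[0], [s.layers[n].values[2, 3] for n in LAYER_ORDER])
        np.testing.assert_array_equal(y, [0.5, 0.7])
        np.testing.assert_array_equal(regions, ["mining", "non_mining"])

    def test_nodata_rows_dropped_with_warning(self, rng):
        s = toy_stack(rng, n=6)
        v = s.layers["river_density"].values.copy()
        v[2, 3] = np.nan
        s.layers["river_density"] = Grid(s.spec, v, nodata=np.nan)
        spec = s.spec
        X, Y = spec.cell_centres()
        samples = [ScoredSample(float(X[2, 3]), float(Y[2, 3]), "mining",
                                0.5, "field_survey_synthetic"),
                   ScoredSample(float(X[0, 0]), float(Y[0, 0]), "non_mining",
                                0.7, "standard_ei")]
        with pytest.warns(UserWarning, match="dropped 1"):
            Xm, y, _ = extract_training(s, samples)
        assert len(y) == 1

    def test_all_nodata_raises(self, rng):
        s = toy_stack(rng, n=3)
        v = np.full(s.spec.shape, np.nan)
        s.layers["river_density"] = Grid(s.spec, v, nodata=np.nan)
        X, Y = s.spec.cell_centres()
        samples = [ScoredSample(float(X[0, 0]), float(Y[0, 0]), "mining",
                                0.5, "x")]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no usable"):
                extract_training(s, samples)


class TestTrainModel:
    def _linear_data(self, rng, n=120):
        X = rng.random((n, 9))
        y = np.clip(X[:, :3] @ np.array([0.5, 0.3, 0.2]), 0, 1)
        return X, y

    @pytest.mark.parametrize("mtype", ["svm", "cart", "c50"])
    def test_fits_and_predicts_in_range(self, rng, mtype):
        X, y = self._linear_data(rng)
        model = train_model(X, y, mtype, seed=0, region="mining")
        pred = model.predict(X)
        assert pred.shape == (len(X),)
        assert pred.min() >= 0.0 and pred.max() <= 1.0
        assert model.model_type == mtype

    def test_svm_recovers_linear_signal(self, rng):
        X, y = self._linear_data(rng)
        model = train_model(X, y, "svm", seed=0, region="mining")
        rmse = np.sqrt(np.mean((model.predict(X) - y) ** 2))
        assert rmse < 0.05

    def test_too_few_rows_raise(self, rng):
        X, y = self._linear_data(rng, n=10)
        with pytest.raises(ValueError, match="20"):
            train_model(X, y, "svm", seed=0, region="mining")

    def test_constant_target_warns_and_is_constant(self, rng):
        X = rng.random((30, 9))
        y = np.full(30, 0.4)
        with pytest.warns(UserWarning, match="constant"):
            model = train_model(X, y, "svm", seed=0, region="mining")
        np.testing.assert_allclose(model.predict(rng.random((5, 9))), 0.4)

    def test_unknown_type(self, rng):
        X, y = self._linear_data(rng)
        with pytest.raises(ValueError, match="model type"):
            train_model(X, y, "boost", seed=0, region="mining")

    def test_deterministic(self, rng):
        X, y = self._linear_data(rng)
        p1 = train_model(X, y, "svm", seed=3, region="m").predict(X[:7])
        p2 = train_model(X, y, "svm", seed=3, region="m").predict(X[:7])
        np.testing.assert_array_equal(p1, p2)


class TestClassAgreement:
    def test_counts_matching_classes(self):
        a = np.array([0.1, 0.3, 0.5, 0.9])
        b = np.array([0.15, 0.35, 0.7, 0.95])
        assert class_agreement(a, b) == pytest.approx(0.75)


class TestSelectAndFuse:
    def test_best_model_per_region_composes_map(self, rng, small_layers,
                                                small_scene):
        samples = make_samples(small_scene, n_non_mining=120, n_mining=60,
                               seed=9, noise_sd=0.0)
        model = EcoAssessment(small_layers.stack, samples, small_layers.mask,
                              small_scene.land_use)
        res = model.fit(seed=1)
        sel = res.selection
        assert set(sel) == {"mining", "non_mining"}
        for region, rec in sel.items():
            assert rec["selected"] in rec["candidates"]
            best_acc = max(v["accuracy_pct"]
                           for v in rec["candidates"].values())
            assert rec["accuracy_pct"] == pytest.approx(best_acc)
        # fused map: non-mining cells predicted by the non-mining model
        m = small_layers.mask
        Xfull = small_layers.stack.as_matrix()
        nm_model = res.models["non_mining"][sel["non_mining"]["selected"]]
        np.testing.assert_allclose(
            res.score.values.ravel()[m.non_mining.ravel()],
            nm_model.predict(Xfull[m.non_mining.ravel()]), atol=1e-12)
        # classes map is the 5-level classification of the score map
        np.testing.assert_array_equal(
            res.classes.values, classify_five(res.score).values)


class TestTables:
    def test_accuracy_table_pooled_rows(self, rng, small_layers, small_scene):
        samples = make_samples(small_scene, n_non_mining=60, n_mining=30,
                               seed=2)
        res = EcoAssessment(small_layers.stack, samples, small_layers.mask,
                            small_scene.land_use).fit(seed=0)
        df = res.accuracy
        assert set(df.columns) == {"region", "land_use", "n", "accuracy_pct"}
        pooled = df[df["land_use"] == "all"]
        assert set(pooled["region"]) == {"mining", "non_mining"}
        # pooled n equals the sum over the per-class rows
        for region, sub in df[df["land_use"] != "all"].groupby("region"):
            n_all = pooled.loc[pooled["region"] == region, "n"].iloc[0]
            assert sub["n"].sum() == n_all

    def test_pearson_nan_for_constant_layer(self, rng):
        s = toy_stack(rng, n=5)
        s.layers["solid_waste"] = Grid(s.spec, np.zeros(s.spec.shape))
        score = Grid(s.spec, rng.random(s.spec.shape))
        df = pearson_table(score, s)
        row = df[df["layer"] == "solid_waste"]["pearson_r"].iloc[0]
        assert np.isnan(row)

    def test_pearson_matches_scipy(self, rng):
        from scipy import stats
        s = toy_stack(rng, n=6)
        score = Grid(s.spec, rng.random(s.spec.shape))
        df = pearson_table(score, s).set_index("layer")
        for name in LAYER_ORDER:
            expected = stats.pearsonr(
                score.values.ravel(),
                s.layers[name].values.ravel()).statistic
            assert df.loc[name, "pearson_r"] == pytest.approx(expected)


class TestEcoAssessment:
    def test_bad_holdout(self, rng, small_layers, small_scene):
        with pytest.raises(ValueError, match="holdout"):
            EcoAssessment(small_layers.stack, [], small_layers.mask,
                          small_scene.land_use, holdout_frac=1.5)

    def test_summary_mentions_selection_and_classes(self, small_layers,
                                                    small_scene):
        samples = make_samples(small_scene, n_non_mining=60, n_mining=30,
                               seed=2)
        res = EcoAssessment(small_layers.stack, samples, small_layers.mask,
                            small_scene.land_use).fit(seed=0)
        text = res.summary()
        assert "mining" in text and "Pearson" in text
        assert "Class shares" in text

    def test_class_share_sums_to_one(self, small_layers, small_scene):
        samples = make_samples(small_scene, n_non_mining=60, n_mining=30,
                               seed=2)
        res = EcoAssessment(small_layers.stack, samples, small_layers.mask,
                            small_scene.land_use).fit(seed=0)
        assert sum(res.class_share().values()) == pytest.approx(1.0)


class TestPipeline:
    def test_single_season_writes_outputs(self, tmp_path, small_scene):
        out = tmp_path / "run"
        result = run_pipeline(small_scene, seasons="spring", seed=0,
                              out_dir=out, n_non_mining=120, n_mining=60)
        assert (out / "spring_score.tif").exists()
        assert (out / "spring_class.tif").exists()
        assert (out / "accuracy.csv").exists()
        assert (out / "pearson.csv").exists()
        assert (out / "provenance.json").exists()
        assert set(result.results) == {"spring"}
        acc = pd.read_csv(out / "accuracy.csv")
        assert (acc["season"] == "spring").all()

    def test_unknown_season_raises(self, small_scene):
        with pytest.raises(ValueError, match="season"):
            compute_layers(small_scene, season="monsoon")
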