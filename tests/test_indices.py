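"""Five sub-indices: printed constants, loop oracles, classification rules."""

import numpy as np
import pytest
import shapely

from minescore.constants import (A_ERO, A_LAK, A_RES, A_RIV, EI_WEIGHTS,
                                 EPS_MAX, HABITAT_WEIGHTS, LANDUSE_WEIGHTS)
from minescore.grids import Grid, GridSpec
from minescore.indices import (EROSION_NONE, EROSION_OTHER, EROSION_SEVERE,
                               BiFactors, EiWeights, HabitatWeights,
                               LandStressParams, RiverDensityParams,
                               biodiversity_index, biological_abundance_index,
                               classify_erosion, classify_five, ei,
                               habitat_quality, land_stress_index,
                               ndvi_from_bands, pollution_loading_index,
                               river_density_index, river_length_grid,
                               vegetation_coverage_index, window_mean)


def window_members(spec, r, c, radius):
    """All (row, col) whose centre lies within `radius` of cell (r, c)."""
    out = []
    for rr in range(spec.n_rows):
        for cc in range(spec.n_cols):
            if ((rr - r) ** 2 + (cc - c) ** 2) * spec.cell_size ** 2 \
                    <= radius ** 2:
                out.append((rr, cc))
    return out


def minmax(a):
    lo, hi = a.min(), a.max()
    return (a - lo) / (hi - lo) if hi > lo else np.zeros_like(a)


class TestEiWeights:
    def test_printed_values(self):
        w = EiWeights()
        assert w.bio_abundance == 0.35
        assert w.vegetation == 0.25
        assert w.river_density == 0.15
        assert w.land_stress == 0.15
        assert w.pollution_load == 0.10
        assert sum(EI_WEIGHTS.values()) == pytest.approx(1.0, abs=1e-15)

    def test_bad_sum_raises(self):
        with pytest.raises(ValueError, match="sum to 1"):
            EiWeights(bio_abundance=0.5)


class TestPrintedConstants:
    def test_lue_table(self):
        assert EPS_MAX["woodland"] == 0.638
        assert EPS_MAX["shrubbery"] == 0.429
        assert EPS_MAX["sparse_woodland"] == 0.475
        for other in ("grassland", "water_wetland", "construction_land",
                      "arable_land", "unutilized_land"):
            assert EPS_MAX[other] == 0.542

    def test_normalization_coefficients(self):
        assert A_RIV == 84.3704
        assert A_LAK == 591.7909
        assert A_RES == 86.387
        assert A_ERO == 236.0436

    def test_habitat_weight_tables(self):
        assert LANDUSE_WEIGHTS[1] == 0.35 and LANDUSE_WEIGHTS[3] == 0.28
        assert HABITAT_WEIGHTS[11] == 0.60 and HABITAT_WEIGHTS[33] == 0.50
        # best attainable product normalizes habitat quality
        assert HabitatWeights().max_product == pytest.approx(0.21)


class TestEiOracle:
    def test_loop_oracle(self, rng):
        spec = GridSpec(20, 20)
        gs = [Grid(spec, rng.random(spec.shape)) for _ in range(5)]
        got = ei(*gs).values
        for r in range(20):
            for c in range(20):
                expected = (0.35 * gs[0].values[r, c]
                            + 0.25 * gs[1].values[r, c]
                            + 0.15 * gs[2].values[r, c]
                            + 0.15 * (1 - gs[3].values[r, c])
                            + 0.10 * (1 - gs[4].values[r, c]))
                assert abs(got[r, c] - expected) < 1e-12

    def test_misaligned(self, rng):
        spec = GridSpec(4, 4)
        g = Grid(spec, rng.random(spec.shape))
        other = Grid(GridSpec(3, 3), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="misaligned"):
            ei(g, g, g, g, other)


class TestHabitatQuality:
    def test_best_habitat_scores_one(self):
        spec = GridSpec(2, 2)
        lu = Grid(spec, np.array([[1, 2], [3, 4]]), kind="categorical")
        hab = Grid(spec, np.array([[11, 21], [33, 41]]), kind="categorical")
        hq = habitat_quality(lu, hab).values
        assert hq[0, 0] == pytest.approx(1.0)  # woodland 0.35 * 0.60 = 0.21
        assert hq[1, 0] == pytest.approx(0.28 * 0.50 / 0.21)

    def test_unknown_subtype_raises(self):
        spec = GridSpec(1, 1)
        lu = Grid(spec, np.array([[1]]), kind="categorical")
        hab = Grid(spec, np.array([[99]]), kind="categorical")
        with pytest.raises(KeyError, match="99"):
            habitat_quality(lu, hab)


class TestBioIndices:
    def test_biodiversity_formula(self, rng):
        spec = GridSpec(6, 6)
        f = BiFactors(npp_mean=Grid(spec, rng.random(spec.shape)),
                      f_pre=Grid(spec, rng.random(spec.shape)),
                      f_tem=Grid(spec, rng.random(spec.shape)),
                      f_alt=Grid(spec, rng.random(spec.shape)))
        raw = biodiversity_index(f, normalize=False).values
        expected = (f.npp_mean.values * f.f_pre.values * f.f_tem.values
                    * (1 - f.f_alt.values))
        np.testing.assert_allclose(raw, expected, atol=1e-15)

    def test_bio_abundance_mean(self, rng):
        spec = GridSpec(5, 5)
        bi = Grid(spec, rng.random(spec.shape))
        hq = Grid(spec, rng.random(spec.shape))
        raw = biological_abundance_index(bi, hq, normalize=False).values
        np.testing.assert_allclose(raw, (bi.values + hq.values) / 2,
                                   atol=1e-15)


class TestNdviAndVegetation:
    def test_ndvi_formula_and_nodata(self):
        spec = GridSpec(1, 3)
        nir = Grid(spec, np.array([[0.5, 0.0, 0.4]]))
        red = Grid(spec, np.array([[0.1, 0.0, 0.4]]))
        nd = ndvi_from_bands(nir, red)
        assert nd.values[0, 0] == pytest.approx((0.5 - 0.1) / 0.6)
        assert np.isnan(nd.values[0, 1])
        assert nd.values[0, 2] == 0.0

    def test_negative_reflectance_raises(self):
        spec = GridSpec(1, 1)
        with pytest.raises(ValueError, match="non-negative"):
            ndvi_from_bands(Grid(spec, [[-0.1]]), Grid(spec, [[0.2]]))

    def test_vegetation_coverage_is_normalized(self, rng):
        spec = GridSpec(5, 5)
        out = vegetation_coverage_index(
            Grid(spec, rng.uniform(-0.2, 0.9, spec.shape))).values
        assert out.min() == 0.0 and out.max() == 1.0


class TestWindowMean:
    def test_loop_oracle(self, rng):
        spec = GridSpec(15, 15)
        vals = rng.random(spec.shape)
        radius = 100.0
        got = window_mean(vals, radius, spec.cell_size)
        for r in range(0, 15, 2):
            for c in range(0, 15, 2):
                mem = window_members(spec, r, c, radius)
                expected = np.mean([vals[rr, cc] for rr, cc in mem])
                assert abs(got[r, c] - expected) < 1e-12


class TestRiverDensity:
    def _scene(self):
        spec = GridSpec(20, 20)
        rivers = [shapely.LineString([(5, -50), (595, -400)]),
                  shapely.LineString([(100, -550), (480, -120), (560, -560)])]
        lakes = [shapely.Point(420, -150).buffer(70)]
        return spec, rivers, lakes

    def test_river_length_grid_oracle(self):
        spec, rivers, _ = self._scene()
        got = river_length_grid(rivers, spec)
        cs = spec.cell_size
        for r in range(spec.n_rows):
            for c in range(spec.n_cols):
                cell = shapely.box(c * cs, -(r + 1) * cs, (c + 1) * cs,
                                   -r * cs)
                expected = sum(line.intersection(cell).length
                               for line in rivers)
                assert abs(got[r, c] - expected) < 1e-9

    def test_full_loop_oracle(self):
        """river_density_index equals an independent looped computation."""
        spec, rivers, lakes = self._scene()
        params = RiverDensityParams(window_radius=150.0)
        resources = 2.5e6
        got = river_density_index(rivers, lakes, resources, spec,
                                  params=params).values
        # independent oracle
        from minescore.grids import rasterize
        cell_area = spec.cell_size ** 2
        riv_len = river_length_grid(rivers, spec)
        lake_area = rasterize(lakes, spec).values * cell_area
        scene_area = spec.n_rows * spec.n_cols * cell_area
        raw = np.zeros(spec.shape)
        for r in range(spec.n_rows):
            for c in range(spec.n_cols):
                mem = window_members(spec, r, c, params.window_radius)
                mriv = np.mean([riv_len[rr, cc] for rr, cc in mem])
                mlak = np.mean([lake_area[rr, cc] for rr, cc in mem])
                raw[r, c] = (params.a_riv * mriv / cell_area
                             + params.a_lak * mlak / cell_area
                             + params.a_res * resources / scene_area) / 3.0
        np.testing.assert_allclose(got, minmax(raw), atol=1e-12)

    def test_window_radius_too_small(self):
        spec, rivers, lakes = self._scene()
        with pytest.raises(ValueError, match="radius"):
            river_density_index(rivers, lakes, 1.0, spec,
                                params=RiverDensityParams(window_radius=10.0))


class TestErosionAndLandStress:
    def _grids(self):
        spec = GridSpec(20, 20)
        lu = Grid(spec, np.full(spec.shape, 2), kind="categorical")
        lu.values[0:4, :] = 5        # construction
        lu.values[10:12, :] = 3      # water
        lu.values[14:16, :] = 1      # woodland
        soil = Grid(spec, np.full(spec.shape, 2), kind="categorical")
        soil.values[:, 0:8] = 3      # cinnamon
        veg = Grid(spec, np.full(spec.shape, 0.4))
        veg.values[18, :] = 0.1      # sparse vegetation -> severe
        veg.values[19, :] = 0.9      # dense vegetation -> none
        return spec, lu, soil, veg

    def test_classification_rules(self):
        spec, lu, soil, veg = self._grids()
        out = classify_erosion(lu, soil, veg).values
        assert (out[0:4, 0:8] == EROSION_SEVERE).all()   # mining land on cinnamon
        assert (out[0:4, 8:] == EROSION_OTHER).all()     # construction, other soil
        assert (out[10:12, 8:] == EROSION_NONE).all()    # water
        assert (out[14:16, 8:] == EROSION_NONE).all()    # woodland
        assert (out[18, 8:] == EROSION_SEVERE).all()     # veg < 0.30
        assert (out[19, 8:] == EROSION_NONE).all()       # veg > 0.50
        # severe precedence over the none rule
        assert (out[18, 0:8] == EROSION_SEVERE).all()

    def test_unknown_soil_raises(self):
        spec, lu, soil, veg = self._grids()
        soil.values[0, 0] = 9
        with pytest.raises(KeyError, match="9"):
            classify_erosion(lu, soil, veg)

    def test_land_stress_loop_oracle(self):
        spec, lu, soil, veg = self._grids()
        erosion = classify_erosion(lu, soil, veg)
        params = LandStressParams(window_radius=150.0)
        got = land_stress_index(erosion, params=params).values
        w = np.select([erosion.values == EROSION_SEVERE,
                       erosion.values == EROSION_OTHER], [0.4, 0.2], 0.0)
        raw = np.zeros(spec.shape)
        for r in range(spec.n_rows):
            for c in range(spec.n_cols):
                mem = window_members(spec, r, c, params.window_radius)
                raw[r, c] = params.a_ero * np.mean([w[rr, cc]
                                                    for rr, cc in mem])
        np.testing.assert_allclose(got, minmax(raw), atol=1e-12)

    def test_constant_erosion_gives_zero_index(self):
        spec = GridSpec(10, 10)
        erosion = Grid(spec, np.full(spec.shape, EROSION_OTHER),
                       kind="categorical")
        out = land_stress_index(erosion,
                                params=LandStressParams(window_radius=100.0))
        assert (out.values == 0.0).all()


class TestPollutionLoading:
    def test_normalized(self, rng):
        spec = GridSpec(5, 5)
        out = pollution_loading_index(
            Grid(spec, rng.uniform(50, 150, spec.shape))).values
        assert out.min() == 0.0 and out.max() == 1.0

    def test_negative_aqi_raises(self):
        spec = GridSpec(1, 1)
        with pytest.raises(ValueError, match="non-negative"):
            pollution_loading_index(Grid(spec, [[-5.0]]))


class TestClassifyFive:
    def test_bins_and_boundaries(self):
        scores = np.array([0.0, 0.2, 0.2000001, 0.4, 0.55, 0.8, 0.81, 1.0])
        out = classify_five(scores)
        np.testing.assert_array_equal(out, [1, 1, 2, 2, 3, 4, 5, 5])

    def test_grid_in_grid_out(self):
        spec = GridSpec(2, 2)
        g = classify_five(Grid(spec, np.array([[0.1, 0.3], [0.5, 0.9]])))
        assert g.kind == "categorical"
        np.testing.assert_array_equal(g.values, [[1, 2], [3, 5]])

    def test_bad_breaks(self):
        with pytest.raises(ValueError, match="breaks"):
            classify_five(np.array([0.5]), breaks=(0.4, 0.3, 0.6, 0.8))
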