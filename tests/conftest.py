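"""Shared fixtures: one small synthetic scene reused across the suite."""

import numpy as np
import pytest

from minescore import SceneConfig, make_scene
from minescore.assessment import compute_layers
from minescore.grids import Grid, GridSpec


@pytest.fixture(scope="session")
def small_scene():
    # 100x100 cells (3 km x 3 km) with two mine sites keeps both the mining
    # and non-mining regions non-empty while staying fast
    return make_scene(SceneConfig(seed=7, n_rows=100, n_cols=100,
                                  n_mine_sites=2))


@pytest.fixture(scope="session")
def small_layers(small_scene):
    return compute_layers(small_scene)


@pytest.fixture
def spec10():
    return GridSpec(10, 10, cell_size=30.0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def grid_of(spec, values, **kw):
    return Grid(spec, np.asarray(values), **kw)
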