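import numpy as np
import pytest

from paleodisp import LandMask, build_grid


@pytest.fixture
def equator_grid():
    """Fine near-equator grid where the metric is essentially flat."""
    return build_grid((0.0, 6.0), (-3.0, 3.0), 0.1)


@pytest.fixture
def small_grid():
    return build_grid((0.0, 10.0), (40.0, 50.0), 0.5)


@pytest.fixture
def all_land(small_grid):
    return LandMask(small_grid, np.ones(small_grid.shape, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
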