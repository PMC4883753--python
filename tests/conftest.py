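import numpy as np
import pytest

from cuticle_course.io_model import ExpressionMatrix, TimeGrid, DEFAULT_GRID
from cuticle_course.synthetic_data import SimConfig


@pytest.fixture
def grid() -> TimeGrid:
    return DEFAULT_GRID


@pytest.fixture
def toy_matrix(grid) -> ExpressionMatrix:
    """Five genes with hand-chosen trajectories over the 7-point grid."""
    fpkm = np.array([
        [0, 0, 10, 0, 0, 0, 0],      # spike at 62 hr
        [1, 1, 1, 1, 1, 1, 1],       # flat, barely at the floor
        [2, 50, 60, 55, 40, 30, 20],  # early rise then drift
        [100, 80, 60, 40, 20, 10, 5],  # monotone fall
        [0, 0, 0, 0, 0, 0, 0],       # silent
    ])
    return ExpressionMatrix(("spike62", "flat1", "early", "fall", "silent"),
                            grid, fpkm)


@pytest.fixture
def small_config() -> SimConfig:
    return SimConfig(seed=7, n_genes=100)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
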