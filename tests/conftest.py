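import numpy as np
import pytest

from platevol.simulate.mesh import build_mesh
from platevol.simulate.surface import sample_radial_grid, smooth_grid


@pytest.fixture(scope="session")
def random_smoothed_grid():
    """A representative smoothed radial field (64 x 32, moderate spread)."""
    return smooth_grid(sample_radial_grid(10.0, 1.5, 64, 32, seed=3))


@pytest.fixture(scope="session")
def random_food_mesh(random_smoothed_grid):
    return build_mesh(random_smoothed_grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
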