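import numpy as np
import pytest

from bmusim import default_params
from bmusim.lattice import make_initial_bmu


@pytest.fixture
def params():
    return default_params()


@pytest.fixture
def toy_params():
    """A 20x30 grid small enough for exhaustive checks."""
    return default_params(grid_width_um=200.0, grid_height_um=300.0,
                          msc_count=6, init_pob=4, init_poc=4, pob_max=20,
                          poc_max=20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_grid(toy_params, rng):
    return make_initial_bmu(toy_params, rng)
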