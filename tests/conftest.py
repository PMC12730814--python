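import numpy as np
import pytest

from relaxmap import default_acquisition_grids, make_three_tissue_phantom


@pytest.fixture(scope="session")
def grids():
    """(T1 grid, T2 grid) of the default acquisition protocol."""
    return default_acquisition_grids()


@pytest.fixture(scope="session")
def t1_grid(grids):
    return grids[0]


@pytest.fixture(scope="session")
def t2_grid(grids):
    return grids[1]


@pytest.fixture()
def noiseless_phantom():
    """64 x 64 three-tissue phantom with zero noise."""
    return make_three_tissue_phantom(shape=(64, 64), seed=0, noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
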