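import numpy as np
import pytest

from hyperbiopsy import make_synthetic_library, make_wavelength_grid
from hyperbiopsy.spectral import load_literature_library


@pytest.fixture(scope="session")
def grid79():
    return make_wavelength_grid(510, 900, 5)


@pytest.fixture(scope="session")
def grid_nir(grid79):
    return grid79.subgrid(740, 900)


@pytest.fixture(scope="session")
def synth_library(grid79):
    return make_synthetic_library(grid79, seed=0)


@pytest.fixture(scope="session")
def literature_library():
    return load_literature_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
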