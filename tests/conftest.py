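import numpy as np
import pytest

from kelpshift.grid import GridSpec
from kelpshift.synthetic import make_world


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    """80 x 60 cell window, 4 degrees of latitude."""
    return GridSpec(lon_min=-2.0, lon_max=1.0, lat_min=50.0, lat_max=54.0, resolution=0.05)


@pytest.fixture(scope="session")
def small_world(small_grid):
    """Seeded world whose planted thermal band (17 +/- ~2 degC at 10% of max)
    sits in the middle of the window's 13-21 degC temperature span."""
    return make_world(small_grid, {"warm3": 3.0}, seed=5, t_south=21.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
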