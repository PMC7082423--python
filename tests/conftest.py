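import numpy as np
import pytest

import popglass as pg
from popglass import maxent


@pytest.fixture(scope="session")
def frustrated6():
    """Small planted frustrated model, fully enumerable."""
    return pg.make_frustrated_model(6, 0.5, -2.0, seed=11)


@pytest.fixture(scope="session")
def frustrated10():
    return pg.make_frustrated_model(10, 0.6, -2.0, seed=21)


@pytest.fixture(scope="session")
def raster6(frustrated6):
    return pg.sample_ising(frustrated6, 4000, seed=12)


@pytest.fixture(scope="session")
def stats6(raster6):
    return pg.empirical_stats(raster6)


@pytest.fixture(scope="session")
def mode_truth():
    """Well-separated planted modes: N=20, M=3, disjoint 5-neuron sets."""
    return pg.make_planted_modes(20, 3, 5, 0.5, 0.02, 0.75, seed=3)


@pytest.fixture(scope="session")
def mode_raster(mode_truth):
    raster, labels = pg.sample_mode_raster(mode_truth, 3000, seed=4)
    return raster, labels


@pytest.fixture(scope="session")
def two_community_model():
    """Two frustrated communities: positive within, negative across."""
    J = np.zeros((12, 12))
    J[:6, :6] = 0.9
    J[6:, 6:] = 0.9
    J[:6, 6:] = J[6:, :6] = -0.6
    np.fill_diagonal(J, 0.0)
    return maxent.MaxEntModel(np.full(12, -2.0), J)
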