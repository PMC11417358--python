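import numpy as np
import pytest

from nucleograph.maps import DensityMap, OrthoGrid
from nucleograph.synthetic import DensitySpec, DuplexSpec, make_density, make_duplex


@pytest.fixture(scope="session")
def duplex10():
    """A 10 bp idealized B-form duplex shared across tests."""
    return make_duplex(DuplexSpec(n_base_pairs=10), seed=11)


@pytest.fixture(scope="session")
def duplex10_map(duplex10):
    """Noise-free Gaussian-atom density for the shared duplex."""
    return make_density(duplex10, DensitySpec(), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_map(rng):
    """A small orthorhombic density map with random values."""
    values = rng.normal(size=(10, 12, 14))
    cell = (10 * 0.8, 12 * 0.8, 14 * 0.8, 90.0, 90.0, 90.0)
    return DensityMap(values=values, cell=cell, origin=np.array([1.0, -2.0, 3.0]))


@pytest.fixture()
def ortho_grid(rng):
    return OrthoGrid(values=rng.normal(size=(20, 20, 20)), spacing=0.7,
                     origin=np.zeros(3))
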