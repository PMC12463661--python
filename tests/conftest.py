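import numpy as np
import pytest

from fourierforce import benchmarks
from fourierforce.descriptors import DescriptorSpec
from fourierforce.potential import fit_potential
from fourierforce.structures_io import AtomicConfiguration


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_cluster(rng, n_atoms=6, species=("Ar",), scale=3.5, min_dist=2.5):
    """Well-separated random cluster for derivative/invariance tests."""
    while True:
        pos = rng.uniform(0.0, scale * n_atoms ** (1 / 3) * 1.3, size=(n_atoms, 3))
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_dist:
            break
    tags = [species[i % len(species)] for i in range(n_atoms)]
    return AtomicConfiguration(pos, tags)


@pytest.fixture
def cluster6(rng):
    return random_cluster(rng, n_atoms=6)


@pytest.fixture(scope="session")
def lj_spec():
    return benchmarks.lj_benchmark_spec()


@pytest.fixture(scope="session")
def small_lj_potential():
    """A quickly trained LJ model shared by prediction/MD tests."""
    train = benchmarks.lj_benchmark_dataset(24, seed=101)
    val = benchmarks.lj_benchmark_dataset(12, seed=102)
    potential, _ = fit_potential(train, val, spec=benchmarks.lj_benchmark_spec(),
                                 n_features=256, seed=3)
    return potential
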