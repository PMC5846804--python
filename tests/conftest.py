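import numpy as np
import pytest

from conncluster import ToySpec, simulate


@pytest.fixture(scope="session")
def toy_default():
    """One toy realization at the default parameterization (4x25, 10/30)."""
    return simulate(ToySpec(seed=11))


@pytest.fixture(scope="session")
def toy_small():
    """A small, fast toy stack: 2 groups of 6, 6 nodes, 3 informative."""
    spec = ToySpec(group_sizes=(6, 6), n_nodes=6, n_informative=3,
                   within_interval=(0.05, 0.2), between_interval=(0.5, 0.9),
                   seed=5)
    return simulate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_distance_matrix(rng, m):
    """Euclidean distances of random planar points: symmetric, metric, zero diag."""
    X = rng.random((m, 2))
    D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    np.fill_diagonal(D, 0.0)
    return D
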