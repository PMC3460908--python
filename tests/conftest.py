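import numpy as np
import pytest

from richclubnet.network_core import ConnectionMatrix
from richclubnet.synthetic import SyntheticSpec, fixture_library, generate


def make_net(adjacency, prefix="n") -> ConnectionMatrix:
    a = np.asarray(adjacency, dtype=np.uint8)
    return ConnectionMatrix(a, tuple(f"{prefix}{i}" for i in range(a.shape[0])))


def random_digraph(rng, n=None, p=None) -> ConnectionMatrix:
    """Random directed graph with at least two edges."""
    n = n or int(rng.integers(3, 7))
    p = p or float(rng.uniform(0.2, 0.7))
    while True:
        a = (rng.random((n, n)) < p).astype(np.uint8)
        np.fill_diagonal(a, 0)
        if a.sum() >= 2:
            return make_net(a)


@pytest.fixture(scope="session")
def fixtures():
    return fixture_library()


@pytest.fixture(scope="session")
def planted():
    """One macaque-scale planted network shared across tests."""
    net, truth = generate(SyntheticSpec(seed=0))
    return net, truth


@pytest.fixture(scope="session")
def small_planted():
    """A reduced planted network for ensemble-heavy unit tests."""
    spec = SyntheticSpec(n_nodes=100, rc_size=10, seed=1)
    net, truth = generate(spec)
    return net, truth
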