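import numpy as np
import pytest

from multigft.graphs import SignalSet, WeightedGraph, laplacian_from_adjacency


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_weighted_graph(n: int, rng: np.random.Generator, density: float = 0.5) -> WeightedGraph:
    """Random symmetric nonnegative adjacency with zero diagonal."""
    w = rng.random((n, n)) * (rng.random((n, n)) < density)
    w = np.triu(w, k=1)
    return WeightedGraph(w + w.T)


@pytest.fixture
def path3_laplacian():
    """Unit-weight 3-node path graph Laplacian."""
    w = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return laplacian_from_adjacency(WeightedGraph(w))


@pytest.fixture
def small_signals(rng):
    return SignalSet(rng.standard_normal((6, 11)))
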