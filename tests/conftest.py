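import numpy as np
import pytest

from connectropy import BinaryGraph


def graph_from_edges(n, edges):
    A = np.zeros((n, n), dtype=int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return BinaryGraph(A)


@pytest.fixture
def path3():
    """Path graph 0-1-2."""
    return graph_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def k3():
    return graph_from_edges(3, [(0, 1), (0, 2), (1, 2)])


@pytest.fixture
def star4():
    """Star: center 0 with leaves 1, 2, 3."""
    return graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def lollipop():
    """Triangle 0-1-2 with pendant node 3 attached to 0."""
    return graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (0, 3)])


def random_connected_graph(n, p, rng):
    """Rejection-sample a connected Erdős–Rényi graph."""
    from connectropy.io import largest_component

    while True:
        iu, ju = np.triu_indices(n, k=1)
        A = np.zeros((n, n), dtype=int)
        e = rng.random(iu.size) < p
        A[iu[e], ju[e]] = 1
        A[ju[e], iu[e]] = 1
        g = BinaryGraph(A)
        if g.is_connected():
            return g
        g = largest_component(g)
        if g.n_nodes >= max(3, int(0.8 * n)):
            return g
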