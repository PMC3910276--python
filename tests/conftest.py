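import networkx as nx
import pytest

from interolog.topology import graph_from_edges


@pytest.fixture
def triangle():
    return graph_from_edges([(1, 2), (2, 3), (1, 3)])


@pytest.fixture
def star5():
    """Star on 5 nodes: center 'c', four leaves."""
    return graph_from_edges([("c", f"l{i}") for i in range(1, 5)])


@pytest.fixture
def path3():
    return graph_from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def square_diag():
    """4-cycle with one diagonal: edges {12, 23, 34, 41, 13}."""
    return graph_from_edges([(1, 2), (2, 3), (3, 4), (4, 1), (1, 3)])


def random_simple_graphs(n_graphs, max_n=50, seed=0):
    """Random ER graphs of varied size/density for oracle comparisons."""
    import numpy as np

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_graphs):
        n = int(rng.integers(2, max_n + 1))
        max_e = n * (n - 1) // 2
        e = int(rng.integers(0, max_e + 1))
        out.append(nx.gnm_random_graph(n, e, seed=int(rng.integers(2**31))))
    return out
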