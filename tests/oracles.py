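"""Independent brute-force oracles for graph metrics.

Deliberately naive (triple loops, Floyd–Warshall) and independent of
both the package implementation and networkx's metric routines, so they
can arbitrate disagreements.
"""

from collections import Counter

import numpy as np


def brute_degree_distribution(g):
    degs = [len(list(g.neighbors(u))) for u in g]
    counts = Counter(degs)
    n = len(degs)
    return dict(counts), {k: c / n for k, c in counts.items()}


def brute_knn(g):
    """Direct evaluation of k_nn,i = (1/k_i) * sum_j a_ij k_j."""
    deg = {u: len(list(g.neighbors(u))) for u in g}
    out = {}
    for u in g:
        if deg[u] == 0:
            continue
        out[u] = sum(deg[v] for v in g.neighbors(u)) / deg[u]
    return out


def brute_clustering(g):
    """C_i = 2 e_i / (k_i (k_i - 1)) by explicit neighbor-pair enumeration."""
    out = {}
    for u in g:
        nbrs = list(g.neighbors(u))
        k = len(nbrs)
        if k < 2:
            out[u] = 0.0
            continue
        e_i = 0
        for i in range(k):
            for j in range(i + 1, k):
                if g.has_edge(nbrs[i], nbrs[j]):
                    e_i += 1
        out[u] = 2.0 * e_i / (k * (k - 1))
    return out


def floyd_warshall_avg_path(g, nodes=None):
    """Average all-pairs hop count via Floyd–Warshall on a dense matrix.

    Returns None when the node set is not connected.
    """
    nodes = sorted(nodes if nodes is not None else g.nodes(), key=str)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    big = n + 1
    d = np.full((n, n), big, dtype=np.int64)
    np.fill_diagonal(d, 0)
    for u, v in g.edges():
        if u in idx and v in idx:
            d[idx[u], idx[v]] = 1
            d[idx[v], idx[u]] = 1
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    if (d >= big).any():
        return None
    return d.sum() / (n * (n - 1))
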