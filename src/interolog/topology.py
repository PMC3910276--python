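"""Topological characterization of an undirected interaction network.

The network is a simple undirected graph whose nodes are genes (unigenes)
and whose edges are inferred interactions.  This module computes, per
connected component or for the whole graph:

* the degree distribution ``P(k) = N(k) / N`` and its log-log
  least-squares power-law fit ``P(k) = a * k^(-gamma)``,
* the average nearest-neighbor degree ``k_nn,i = (1/k_i) * sum_j a_ij k_j``
  and its per-degree curve ``k_nn(k)`` (degree correlation /
  assortativity diagnostic),
* per-node clustering ``C_i = 2 e_i / (k_i (k_i - 1))``, the per-degree
  curve ``C(k)`` and the network average ``C``,
* the average shortest path length ``L`` (mean number of edges on the
  shortest path, over all unordered pairs of a connected component).

Graphs are :class:`networkx.Graph` instances throughout; the per-node
metrics are computed directly from adjacency sets rather than delegated,
so tests can cross-check them against independent oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DegreeDistribution",
    "PowerLawFit",
    "TopologySummary",
    "graph_from_edges",
    "connected_components",
    "giant_component",
    "degree_distribution",
    "fit_power_law",
    "nearest_neighbor_degree",
    "clustering_coefficients",
    "average_shortest_path",
    "topology_summary",
    "read_edge_tsv",
    "write_edge_tsv",
]


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class DegreeDistribution:
    """Observed degree spectrum of a graph.

    ``counts[k]`` is N(k), the number of nodes with degree k;
    ``probs[k] = N(k) / N``.  Degrees with zero count are omitted.
    """

    counts: Mapping[int, int]
    probs: Mapping[int, float]
    n_nodes: int

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.counts)
        return pd.DataFrame(
            {"degree": ks, "count": [self.counts[k] for k in ks],
             "probability": [self.probs[k] for k in ks]}
        )


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares fit of P(k) = a * k^(-gamma) in log10-log10 space."""

    prefactor: float
    exponent: float
    fit_domain: tuple[int, ...]

    def predict(self, k: float) -> float:
        return self.prefactor * k ** (-self.exponent)


@dataclass
class TopologySummary:
    """All topology metrics for one graph, computed on its giant component."""

    n_nodes: int
    n_edges: int
    n_components: int
    component_sizes: list[int]
    giant_nodes: int
    giant_edges: int
    degree_dist: DegreeDistribution
    power_law: PowerLawFit | None
    knn_per_node: dict
    knn_curve: dict[int, float]
    clustering_per_node: dict
    clustering_curve: dict[int, float]
    clustering: float
    avg_path_length: float
    ck_slope: float | None = None  # OLS slope of log10 C(k) vs log10 k

    def to_json(self) -> str:
        payload = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_components": self.n_components,
            "component_sizes": self.component_sizes,
            "giant_nodes": self.giant_nodes,
            "giant_edges": self.giant_edges,
            "clustering_coefficient": self.clustering,
            "avg_shortest_path": self.avg_path_length,
            "power_law": None
            if self.power_law is None
            else {
                "prefactor": self.power_law.prefactor,
                "exponent": self.power_law.exponent,
                "n_degrees": len(self.power_law.fit_domain),
            },
            "ck_slope": self.ck_slope,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# graph construction / io


def graph_from_edges(edges: Iterable[tuple]) -> nx.Graph:
    """Build a simple undirected graph, dropping self-loops and duplicates."""
    g = nx.Graph()
    for u, v in edges:
        if u == v:
            continue
        g.add_edge(u, v)
    return g


def read_edge_tsv(path) -> nx.Graph:
    """Read a 2-column (plus optional score) TSV edge list into a graph."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"edge table {path!r} needs at least two columns")
    return graph_from_edges(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_edge_tsv(g: nx.Graph, path) -> None:
    rows = sorted(tuple(sorted(map(str, e))) for e in g.edges())
    pd.DataFrame(rows, columns=["node_a", "node_b"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# components


def _component_key(g: nx.Graph, comp: set):
    # larger node count first, then more edges, then smallest member id
    sub_edges = g.subgraph(comp).number_of_edges()
    return (-len(comp), -sub_edges, min(str(n) for n in comp))


def connected_components(g: nx.Graph) -> list[set]:
    """Connected components, largest first.

    Ties in node count are broken by edge count, then by the smallest
    (lexicographic) member id, so the "giant" component is deterministic.
    """
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: _component_key(g, c))
    return comps


def giant_component(g: nx.Graph) -> nx.Graph:
    """Subgraph copy of the largest connected component (empty graph in, empty out)."""
    comps = connected_components(g)
    if not comps:
        return nx.Graph()
    return g.subgraph(comps[0]).copy()


# ---------------------------------------------------------------------------
# degree distribution and power-law fit


def degree_distribution(g: nx.Graph) -> DegreeDistribution:
    """P(k) = N(k)/N over observed degrees; zero-count degrees omitted."""
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("degree distribution of an empty graph is undefined")
    counts: dict[int, int] = {}
    for _, k in g.degree():
        counts[k] = counts.get(k, 0) + 1
    probs = {k: c / n for k, c in counts.items()}
    return DegreeDistribution(counts=counts, probs=probs, n_nodes=n)


def fit_power_law(dist: DegreeDistribution) -> PowerLawFit:
    """Unweighted, unbinned OLS of log10 P(k) on log10 k.

    Only strictly positive degrees with nonzero probability enter the fit.
    Returns ``a = 10**intercept`` and ``gamma = -slope``.
    """
    ks = sorted(k for k, p in dist.probs.items() if k > 0 and p > 0)
    if len(ks) < 2:
        raise ValueError("power-law fit needs at least two positive degrees")
    x = np.log10(np.asarray(ks, dtype=float))
    y = np.log10(np.asarray([dist.probs[k] for k in ks], dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    return PowerLawFit(
        prefactor=float(10.0**intercept),
        exponent=float(-slope),
        fit_domain=tuple(ks),
    )


def _loglog_slope(curve: Mapping[int, float]) -> float | None:
    pts = [(k, v) for k, v in curve.items() if k > 0 and v > 0]
    if len(pts) < 2:
        return None
    x = np.log10([k for k, _ in pts])
    y = np.log10([v for _, v in pts])
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# degree correlation


def nearest_neighbor_degree(g: nx.Graph) -> tuple[dict, dict[int, float]]:
    """Average nearest-neighbor degree per node and its per-degree curve.

    ``k_nn,i = (1/k_i) * sum over neighbors j of k_j``; isolated nodes are
    excluded.  The curve value at k is the arithmetic mean of k_nn,i over
    nodes of degree k (no logarithmic binning).
    """
    deg = dict(g.degree())
    per_node: dict = {}
    for u in g:
        k = deg[u]
        if k < 1:
            continue
        per_node[u] = sum(deg[v] for v in g[u]) / k
    curve: dict[int, list[float]] = {}
    for u, knn in per_node.items():
        curve.setdefault(deg[u], []).append(knn)
    return per_node, {k: float(np.mean(v)) for k, v in sorted(curve.items())}


# ---------------------------------------------------------------------------
# clustering


def clustering_coefficients(
    g: nx.Graph, include_low_degree: bool = True
) -> tuple[dict, dict[int, float], float]:
    """Per-node clustering C_i, per-degree curve C(k), and network average C.

    ``C_i = 2 e_i / (k_i (k_i - 1))`` where e_i is the number of edges among
    the neighbors of i.  Nodes of degree < 2 are assigned C_i = 0 and, by
    default, included in the network average; set ``include_low_degree=False``
    to average over degree >= 2 nodes only.  C(k) always averages over
    degree-k nodes with k >= 2.
    """
    adj = {u: set(g[u]) for u in g}
    per_node: dict = {}
    for u in g:
        nbrs = adj[u]
        k = len(nbrs)
        if k < 2:
            per_node[u] = 0.0
            continue
        links = 0
        for v in nbrs:
            # count each neighbor-neighbor edge once
            links += len(adj[v] & nbrs)
        e_i = links // 2
        per_node[u] = 2.0 * e_i / (k * (k - 1))

    deg = dict(g.degree())
    by_degree: dict[int, list[float]] = {}
    for u, c in per_node.items():
        if deg[u] >= 2:
            by_degree.setdefault(deg[u], []).append(c)
    curve = {k: float(np.mean(v)) for k, v in sorted(by_degree.items())}

    if include_low_degree:
        values = list(per_node.values())
    else:
        values = [c for u, c in per_node.items() if deg[u] >= 2]
    network_c = float(np.mean(values)) if values else 0.0
    return per_node, curve, network_c


# ---------------------------------------------------------------------------
# shortest paths


def average_shortest_path(g: nx.Graph, component: Iterable | None = None) -> float:
    """Mean shortest-path hop count over all unordered node pairs.

    Distances are numbers of edges traversed, computed by breadth-first
    search from every node of the (connected) component.  Raises if the
    supplied node set is not connected within ``g``.
    """
    nodes = set(component) if component is not None else set(g.nodes())
    if len(nodes) < 2:
        raise ValueError("average shortest path needs a component with >= 2 nodes")
    sub = g.subgraph(nodes)
    total = 0
    n = len(nodes)
    for u in nodes:
        dists = nx.single_source_shortest_path_length(sub, u)
        if len(dists) != n:
            raise ValueError("component is not connected; cannot average distances")
        total += sum(dists.values())
    # each unordered pair counted twice in the double sum
    return total / (n * (n - 1))


# ---------------------------------------------------------------------------
# bundle


def topology_summary(g: nx.Graph, include_low_degree: bool = True) -> TopologySummary:
    """All metrics for ``g``; per-node metrics and L on the giant component.

    The power-law fit of P(k) and the C(k) ~ k^-1 guideline slope are
    reported when at least two usable degrees exist, else left as None.
    """
    comps = connected_components(g)
    if not comps:
        raise ValueError("cannot summarize an empty graph")
    giant = g.subgraph(comps[0])

    dist = degree_distribution(giant)
    try:
        fit = fit_power_law(dist)
    except ValueError:
        fit = None
    knn_i, knn_k = nearest_neighbor_degree(giant)
    c_i, c_k, c_net = clustering_coefficients(giant, include_low_degree)
    if giant.number_of_nodes() >= 2:
        length = average_shortest_path(giant)
    else:
        length = 0.0
    return TopologySummary(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_components=len(comps),
        component_sizes=[len(c) for c in comps],
        giant_nodes=giant.number_of_nodes(),
        giant_edges=giant.number_of_edges(),
        degree_dist=dist,
        power_law=fit,
        knn_per_node=knn_i,
        knn_curve=knn_k,
        clustering_per_node=c_i,
        clustering_curve=c_k,
        clustering=c_net,
        avg_path_length=length,
        ck_slope=_loglog_slope(c_k),
    )


def plot_loglog_panels(summary: TopologySummary, path) -> None:
    """Optional three-panel log-log figure: P(k), k_nn(k), C(k) with fits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    dd = summary.degree_dist
    ks = sorted(k for k in dd.probs if k > 0)
    axes[0].loglog(ks, [dd.probs[k] for k in ks], "o", ms=4)
    if summary.power_law is not None:
        xs = np.array(ks, dtype=float)
        axes[0].loglog(xs, summary.power_law.predict(xs), "r-", lw=1)
    axes[0].set_xlabel("k")
    axes[0].set_ylabel("P(k)")
    for ax, curve, label in (
        (axes[1], summary.knn_curve, "k_nn(k)"),
        (axes[2], summary.clustering_curve, "C(k)"),
    ):
        pts = [(k, v) for k, v in curve.items() if k > 0 and v > 0]
        if pts:
            ax.loglog([p[0] for p in pts], [p[1] for p in pts], "o", ms=4)
        ax.set_xlabel("k")
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
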