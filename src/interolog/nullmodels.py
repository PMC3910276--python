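"""Random-graph null models with matched node and edge counts.

Observed interaction networks are compared against Erdős–Rényi (ER),
Watts–Strogatz (WS) and Barabási–Albert (BA) graphs built with the same
number of nodes N and edges E.  WS and BA cannot hit an arbitrary E
natively, so their constructions are followed by a random edge top-up /
removal step that preserves simplicity and determinism per seed:

* ER: exactly E distinct edges sampled uniformly without replacement.
* WS: ring lattice with even neighbor count kappa = 2*floor(E/N)
  (>= 2), each lattice edge rewired with probability ``p_rewire``,
  then adjusted to exactly E edges.
* BA: preferential attachment with m = max(1, round(E/N)), then
  adjusted to exactly E edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .topology import (
    average_shortest_path,
    clustering_coefficients,
    giant_component,
)

__all__ = ["NullModelRow", "random_graph", "ws_base", "null_model_table"]

MODELS = ("ER", "WS", "BA")


@dataclass(frozen=True)
class NullModelRow:
    """One line of the observed-vs-null comparison table."""

    model: str  # "giant", "ER", "WS" or "BA"
    clustering: float
    avg_path_length: float
    replicates: int
    clustering_sd: float
    path_length_sd: float


def _check_feasible(n: int, e: int) -> None:
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got n={n}")
    max_e = n * (n - 1) // 2
    if not 0 <= e <= max_e:
        raise ValueError(f"e={e} infeasible for a simple graph on n={n} nodes (max {max_e})")


def _adjust_edge_count(g: nx.Graph, e: int, rng: np.random.Generator) -> None:
    """Add random non-edges or remove random edges until g has exactly e edges."""
    n = g.number_of_nodes()
    nodes = sorted(g.nodes())
    while g.number_of_edges() > e:
        edges = sorted(tuple(sorted(edge)) for edge in g.edges())
        u, v = edges[rng.integers(len(edges))]
        g.remove_edge(u, v)
    if g.number_of_edges() < e:
        max_e = n * (n - 1) // 2
        if e > 0.5 * max_e:
            # dense: enumerate missing pairs instead of rejection sampling
            missing = sorted(
                tuple(sorted((nodes[i], nodes[j])))
                for i in range(n)
                for j in range(i + 1, n)
                if not g.has_edge(nodes[i], nodes[j])
            )
            pick = rng.choice(len(missing), size=e - g.number_of_edges(), replace=False)
            for idx in sorted(pick):
                g.add_edge(*missing[idx])
        else:
            while g.number_of_edges() < e:
                u, v = nodes[rng.integers(n)], nodes[rng.integers(n)]
                if u != v and not g.has_edge(u, v):
                    g.add_edge(u, v)


def ws_base(n: int, e: int, p_rewire: float, seed: int) -> tuple[nx.Graph, int]:
    """WS graph before the edge-count adjustment, plus the kappa used.

    At ``p_rewire=0`` this is the plain ring lattice, whose clustering has
    the closed form 3(kappa-2) / (4(kappa-1)).
    """
    kappa = 2 * (e // n)
    kappa = max(2, kappa)
    if kappa >= n:
        kappa = (n - 1) if (n - 1) % 2 == 0 else (n - 2)
        kappa = max(2, kappa)
    g = nx.watts_strogatz_graph(n, kappa, p_rewire, seed=int(seed))
    return g, kappa


def random_graph(
    model: str,
    n: int,
    e: int,
    p_rewire: float = 0.1,
    seed: int | None = None,
) -> nx.Graph:
    """Simple undirected graph with exactly ``n`` nodes and ``e`` edges.

    ``model`` is one of "ER", "WS", "BA"; deterministic for a fixed seed.
    Raises ``ValueError`` when ``e`` exceeds the simple-graph maximum.
    """
    _check_feasible(n, e)
    model = model.upper()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    nx_seed = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss.spawn(1)[0])

    if model == "ER":
        g = nx.gnm_random_graph(n, e, seed=nx_seed)
    elif model == "WS":
        g, _ = ws_base(n, e, p_rewire, nx_seed)
        _adjust_edge_count(g, e, rng)
    else:  # BA
        m = max(1, round(e / n))
        m = min(m, n - 1)
        g = nx.barabasi_albert_graph(n, m, seed=nx_seed)
        _adjust_edge_count(g, e, rng)

    assert g.number_of_nodes() == n and g.number_of_edges() == e
    return g


def null_model_table(
    g: nx.Graph,
    replicates: int = 3,
    seed: int = 0,
    p_rewire: float = 0.1,
    include_low_degree: bool = True,
) -> list[NullModelRow]:
    """Observed graph vs ER/WS/BA nulls of matched N and E.

    The observed graph is reduced to its giant component first; each null
    replicate's C is the network average and its L is computed on the
    replicate's own giant component (nulls may be disconnected).  Replicate
    seeds are derived deterministically from the master seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    giant = giant_component(g)
    n, e = giant.number_of_nodes(), giant.number_of_edges()

    _, _, c_obs = clustering_coefficients(giant, include_low_degree)
    l_obs = average_shortest_path(giant) if n >= 2 else 0.0
    rows = [NullModelRow("giant", c_obs, l_obs, 1, 0.0, 0.0)]

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(MODELS) * replicates) % (2**31)
    idx = 0
    for model in MODELS:
        cs, ls = [], []
        for _ in range(replicates):
            rep = random_graph(model, n, e, p_rewire=p_rewire, seed=int(child_seeds[idx]))
            idx += 1
            _, _, c = clustering_coefficients(rep, include_low_degree)
            rep_giant = giant_component(rep)
            cs.append(c)
            ls.append(average_shortest_path(rep_giant) if rep_giant.number_of_nodes() >= 2 else 0.0)
        ddof = 1 if replicates > 1 else 0
        rows.append(
            NullModelRow(
                model,
                float(np.mean(cs)),
                float(np.mean(ls)),
                replicates,
                float(np.std(cs, ddof=ddof)),
                float(np.std(ls, ddof=ddof)),
            )
        )
    return rows


def null_table_frame(rows: list[NullModelRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model": [r.model for r in rows],
            "clustering_coefficient": [r.clustering for r in rows],
            "avg_shortest_path": [r.avg_path_length for r in rows],
            "replicates": [r.replicates for r in rows],
            "clustering_sd": [r.clustering_sd for r in rows],
            "path_length_sd": [r.path_length_sd for r in rows],
        }
    )
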