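"""The six network measures, with the conventions used throughout the package.

Within-network measures: *edge weight* (the vector of all w_ij) and *node
strength* (s_i = Σ_j w_ij).  Between-network measures: *average strength*
(mean s_i over all nodes, isolated nodes contribute 0), *ASPL* (average
shortest path length with per-step cost 1 − w, averaged over finite-distance
pairs), *average CC* (Barrat-style weighted local clustering, by default on
the 50% strongest edges to avoid ceiling effects), and *modularity* (weighted
Newman Q on Louvain communities).

Undefined values (ASPL with no connected pair, CC with no degree-≥2 node,
modularity of an edgeless graph) are encoded as ``None`` and propagated
explicitly by :func:`measure_panel`.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph import SemanticNetwork

__all__ = [
    "MeasurePanel",
    "node_strengths",
    "average_strength",
    "aspl",
    "average_cc",
    "modularity_q",
    "modularity_louvain",
    "measure_panel",
    "BETWEEN_MEASURES",
    "WITHIN_MEASURES",
]

BETWEEN_MEASURES = ("average_strength", "aspl", "average_cc", "modularity")
WITHIN_MEASURES = ("edge_weight", "node_strength")


def node_strengths(net: SemanticNetwork) -> pd.Series:
    """s_i = Σ_j w_ij for every node (0 for isolated nodes), node-ordered."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    return pd.Series(
        {n: sum(net.weight(n, m) for m in net.neighbors(n)) for n in net.nodes}, dtype=float
    )


def average_strength(net: SemanticNetwork) -> float:
    return float(node_strengths(net).mean())


def aspl(net: SemanticNetwork) -> float | None:
    """Average shortest path length with per-step cost 1 − w.

    Averaged over all ordered node pairs with a finite path; ``None`` when no
    such pair exists.  Zero-cost steps (w = 1) are allowed.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    g.add_weighted_edges_from((i, j, 1.0 - w) for i, j, w in net.edges())
    total, n_pairs = 0.0, 0
    for src, dists in nx.all_pairs_dijkstra_path_length(g):
        for dst, d in dists.items():
            if dst != src:
                total += d
                n_pairs += 1
    return total / n_pairs if n_pairs else None


def _adjacency(net: SemanticNetwork) -> tuple[list[str], np.ndarray]:
    nodes = list(net.nodes)
    idx = {n: a for a, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for i, j, wij in net.edges():
        w[idx[i], idx[j]] = wij
        w[idx[j], idx[i]] = wij
    return nodes, w


def average_cc(net: SemanticNetwork, edge_quantile: float | None = 0.5) -> float | None:
    """Barrat weighted clustering coefficient averaged over nodes.

    cc_i = 1 / (s_i (k_i − 1)) · Σ over ordered neighbor pairs (j, h) of
    ((w_ij + w_ih) / 2) a_ij a_ih a_jh, with s_i and k_i taken on the
    filtered graph.  With ``edge_quantile`` (default 0.5) only edges at or
    above that weight quantile are kept — the "50% strongest edges"
    convention that avoids ceiling effects; pass ``None`` to disable.  Nodes
    with fewer than 2 neighbors are excluded from the average; ``None`` when
    no node qualifies.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    _, w = _adjacency(net)
    if edge_quantile is not None and net.n_edges:
        weights = np.array([wij for _, _, wij in net.edges()])
        threshold = np.quantile(weights, edge_quantile)
        w = np.where(w >= threshold, w, 0.0)
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    s = w.sum(axis=1)
    eligible = k >= 2
    if not eligible.any():
        return None
    closed = (w * (a @ a)).sum(axis=1)  # Σ_j w_ij · #common neighbors(i, j)
    cc = closed[eligible] / (s[eligible] * (k[eligible] - 1))
    return float(cc.mean())


def modularity_q(net: SemanticNetwork, communities) -> float:
    """Weighted Newman modularity Q of a given node partition.

    Q = (1/2m) Σ_{i,j} (a_ij − s_i s_j / 2m) δ(c_i, c_j) with a_ij the weight
    matrix and 2m the total weight counted in both directions.  Invariant to
    uniform rescaling of all weights.
    """
    nodes, w = _adjacency(net)
    two_m = w.sum()
    if two_m <= 0:
        raise ValueError("modularity is undefined for an edgeless network")
    idx = {n: a for a, n in enumerate(nodes)}
    s = w.sum(axis=1)
    q = 0.0
    for comm in communities:
        members = np.array([idx[n] for n in comm])
        q += w[np.ix_(members, members)].sum() / two_m - (s[members].sum() / two_m) ** 2
    return float(q)


def modularity_louvain(
    net: SemanticNetwork,
    seed: int = 0,
    resolution: float = 1.0,
    n_restarts: int = 1,
    return_partition: bool = False,
):
    """Louvain communities on the weighted graph, scored by :func:`modularity_q`.

    Louvain is a randomized heuristic: the seed is fixed and, with
    ``n_restarts`` > 1, the best-Q run over seeds seed..seed+n_restarts−1 is
    kept.
    """
    if net.n_edges == 0:
        raise ValueError("modularity is undefined for an edgeless network")
    g = net.to_networkx()
    best_q, best_parts = -np.inf, None
    for t in range(n_restarts):
        parts = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed + t
        )
        q = modularity_q(net, parts)
        if q > best_q:
            best_q, best_parts = q, parts
    if return_partition:
        return best_q, best_parts
    return best_q


@dataclass
class MeasurePanel:
    """All six measures of one network, undefined values as ``None``."""

    edge_weights: pd.Series  # index: (i, j) sorted pairs
    node_strengths: pd.Series
    average_strength: float
    aspl: float | None
    average_cc: float | None
    modularity: float | None

    def between(self) -> dict[str, float | None]:
        return {
            "average_strength": self.average_strength,
            "aspl": self.aspl,
            "average_cc": self.average_cc,
            "modularity": self.modularity,
        }


def measure_panel(
    net: SemanticNetwork,
    edge_quantile: float | None = 0.5,
    seed: int = 0,
    n_restarts: int = 1,
) -> MeasurePanel:
    """Assemble the full measure panel with shared conventions.

    Modularity of an edgeless network is recorded as ``None`` rather than
    raised, so degenerate inferred networks still produce a panel.
    """
    ew = pd.Series({(i, j): w for i, j, w in net.edges()}, dtype=float)
    ns = node_strengths(net)
    try:
        q = modularity_louvain(net, seed=seed, n_restarts=n_restarts)
    except ValueError:
        q = None
    return MeasurePanel(
        edge_weights=ew,
        node_strengths=ns,
        average_strength=float(ns.mean()),
        aspl=aspl(net),
        average_cc=average_cc(net, edge_quantile=edge_quantile),
        modularity=q,
    )
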