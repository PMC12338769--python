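"""Weighted undirected semantic-network data model and I/O.

A :class:`SemanticNetwork` is the common substrate of the whole package: a
labelled, undirected graph whose nodes are words and whose edge weights are
cosine-like relatedness values.  Weights are stored sparsely as a symmetric
adjacency map; an absent pair has weight 0 and only strictly positive weights
are ever stored.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

__all__ = [
    "SemanticNetwork",
    "induced_subgraph",
    "triangle_scores",
    "read_edgelist",
    "write_edgelist",
    "write_graphml",
]

Edge = tuple[str, str]


def _pair(i: str, j: str) -> Edge:
    """Canonical (lexicographically sorted) form of an unordered node pair."""
    return (i, j) if i <= j else (j, i)


class SemanticNetwork:
    """Undirected, weighted, labelled graph of words.

    Parameters
    ----------
    nodes
        Initial node identifiers (words).  Nodes may also be added implicitly
        through :meth:`add_edge`.
    meta
        Provenance tag, one of ``ground-truth``, ``individualized``,
        ``inferred-FA``, ``inferred-RJ`` (free-form strings accepted).
    """

    def __init__(self, nodes: Iterable[str] = (), meta: str | None = None):
        self._adj: dict[str, dict[str, float]] = {}
        self.meta = meta
        for n in nodes:
            self.add_node(n)

    # -- construction -----------------------------------------------------

    def add_node(self, node: str) -> None:
        self._adj.setdefault(str(node), {})

    def add_edge(self, i: str, j: str, weight: float) -> None:
        """Add (or overwrite) the undirected edge i–j.

        Self-loops and non-positive weights are rejected: an absent pair
        already means weight 0.
        """
        i, j = str(i), str(j)
        if i == j:
            raise ValueError(f"self-loop on node {i!r} is not allowed")
        w = float(weight)
        if not math.isfinite(w):
            raise ValueError(f"edge ({i},{j}) has non-finite weight {weight!r}")
        if w <= 0.0:
            raise ValueError(f"edge ({i},{j}) has non-positive weight {w}; omit the pair instead")
        self.add_node(i)
        self.add_node(j)
        self._adj[i][j] = w
        self._adj[j][i] = w

    def remove_edge(self, i: str, j: str) -> None:
        del self._adj[i][j]
        del self._adj[j][i]

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """All node identifiers, lexicographically ordered."""
        return tuple(sorted(self._adj))

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def weight(self, i: str, j: str) -> float:
        """Weight of pair (i, j); 0.0 when the edge is absent."""
        return self._adj.get(i, {}).get(j, 0.0)

    def neighbors(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self._adj[node]))

    def degree(self, node: str) -> int:
        return len(self._adj[node])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate (i, j, weight) with i < j, in lexicographic order."""
        for i in sorted(self._adj):
            for j in sorted(self._adj[i]):
                if i < j:
                    yield i, j, self._adj[i][j]

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges())

    def copy(self, meta: str | None = None) -> "SemanticNetwork":
        out = SemanticNetwork(self._adj, meta=self.meta if meta is None else meta)
        for i, j, w in self.edges():
            out.add_edge(i, j, w)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SemanticNetwork):
            return NotImplemented
        return self.nodes == other.nodes and dict(
            ((i, j), w) for i, j, w in self.edges()
        ) == dict(((i, j), w) for i, j, w in other.edges())

    def __repr__(self) -> str:  # pragma: no cover
        tag = f", meta={self.meta!r}" if self.meta else ""
        return f"SemanticNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges}{tag})"

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges())
        return g


def induced_subgraph(net: SemanticNetwork, nodes: Iterable[str]) -> SemanticNetwork:
    """Restrict `net` to `nodes`, keeping exactly the edges inside the set.

    Raises ``KeyError`` if any requested node is not in the network.
    """
    keep = set(nodes)
    unknown = keep - set(net.nodes)
    if unknown:
        raise KeyError(f"nodes not in network: {sorted(unknown)}")
    out = SemanticNetwork(keep, meta=net.meta)
    for i, j, w in net.edges():
        if i in keep and j in keep:
            out.add_edge(i, j, w)
    return out


def triangle_scores(net: SemanticNetwork) -> dict[Edge, float]:
    """Per-edge triangle score.

    The score of edge e is the sum, over every triangle containing e, of the
    product of the three edge weights of that triangle.  Edges in no triangle
    score 0.
    """
    scores: dict[Edge, float] = {}
    for i, j, w_ij in net.edges():
        common = set(net._adj[i]) & set(net._adj[j])
        ts = 0.0
        for h in common:
            ts += w_ij * net.weight(i, h) * net.weight(j, h)
        scores[_pair(i, j)] = ts
    return scores


# -- on-disk formats ------------------------------------------------------

_COLUMNS = ["node_i", "node_j", "weight"]


def write_edgelist(net: SemanticNetwork, path) -> None:
    """Write the canonical weighted edge-list CSV (header `node_i,node_j,weight`).

    Isolated nodes are not representable in an edge list and are dropped;
    weights are written with shortest round-trip precision so read∘write is
    the identity on edge weights.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for i, j, w in net.edges():
            writer.writerow([i, j, repr(float(w))])


def read_edgelist(path, meta: str | None = None) -> SemanticNetwork:
    """Read a weighted edge-list CSV into a :class:`SemanticNetwork`.

    Duplicate rows for the same unordered pair are collapsed when their
    weights agree; conflicting duplicates, self-loops and non-numeric weights
    raise ``ValueError``.
    """
    df = pd.read_csv(path, dtype={"node_i": str, "node_j": str}, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list {path} lacks required columns {missing}")
    weights = pd.to_numeric(df["weight"], errors="coerce")
    if weights.isna().any():
        bad = df.loc[weights.isna()].iloc[0]
        raise ValueError(f"non-numeric weight {bad['weight']!r} for pair ({bad['node_i']},{bad['node_j']})")
    net = SemanticNetwork(meta=meta)
    seen: dict[Edge, float] = {}
    for i, j, w in zip(df["node_i"], df["node_j"], weights):
        if i == j:
            raise ValueError(f"self-loop row for node {i!r}")
        key = _pair(i, j)
        if key in seen:
            if not math.isclose(seen[key], w, rel_tol=0.0, abs_tol=1e-12):
                raise ValueError(f"conflicting duplicate weights for pair {key}: {seen[key]} vs {w}")
            continue
        seen[key] = float(w)
        net.add_edge(i, j, w)
    return net


def write_graphml(net: SemanticNetwork, path) -> None:
    """GraphML export for interoperability (weights as edge attribute `weight`)."""
    nx.write_graphml(net.to_networkx(), path)
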