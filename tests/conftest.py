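"""Shared fixtures: small hand-built networks and a random-graph factory."""

import numpy as np
import pytest

from semnetsim import SemanticNetwork


def build_net(edges, nodes=(), meta=None) -> SemanticNetwork:
    """Network from an iterable of (i, j, w) plus optional extra nodes."""
    net = SemanticNetwork(nodes, meta=meta)
    for i, j, w in edges:
        net.add_edge(i, j, w)
    return net


def random_net(n_nodes: int, edge_prob: float, rng: np.random.Generator) -> SemanticNetwork:
    """Erdős–Rényi-style weighted graph with Uniform(0.05, 1) weights."""
    names = [f"n{k:02d}" for k in range(n_nodes)]
    net = SemanticNetwork(names)
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            if rng.random() < edge_prob:
                net.add_edge(names[a], names[b], float(rng.uniform(0.05, 1.0)))
    return net


@pytest.fixture
def triangle():
    """Triangle a-b-c, all weights 0.5."""
    return build_net([("a", "b", 0.5), ("a", "c", 0.5), ("b", "c", 0.5)])


@pytest.fixture
def unit_triangle():
    return build_net([("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0)])


@pytest.fixture
def path_abc():
    """Path a-c-b (no a-b edge)."""
    return build_net([("a", "c", 0.6), ("b", "c", 0.7)])
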