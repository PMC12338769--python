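"""Cue-set generators and the factorial study-design grid.

Cue sets are drawn on the *common* ground-truth network and shared by every
simulated individual within an instantiation.  Three generators cover the
range of cue-selection strategies used in behavioral studies:

narrow
    one tight semantic neighborhood — greedy growth by highest average edge
    weight to the already-included cues (single-category designs);
broad
    a random walk across the network — each step adds a random unvisited
    neighbor of the last added node (wide-coverage designs);
mixed
    several broad seeds, each grown into its own tight neighborhood
    (multi-category designs).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .graph import SemanticNetwork

__all__ = [
    "CueSet",
    "DesignConfig",
    "narrow_cues",
    "broad_cues",
    "mixed_cues",
    "generate_cues",
    "enumerate_designs",
    "paper_grid",
]

PARADIGMS = ("free_association", "relatedness_judgment")
CUE_SET_TYPES = ("narrow", "broad", "mixed")


@dataclass(frozen=True)
class CueSet:
    cues: tuple[str, ...]
    type: str
    seed: int
    instantiation_id: int = 0

    def __post_init__(self):
        if len(set(self.cues)) != len(self.cues):
            raise ValueError("cues must be distinct")

    def __len__(self) -> int:
        return len(self.cues)


@dataclass(frozen=True)
class DesignConfig:
    """One cell of the factorial study-design grid."""

    paradigm: str
    cue_set_type: str
    cue_set_size: int
    responses_per_cue: int
    n_instantiations: int = 10
    n_participants: int = 250
    seed: int = 0

    def __post_init__(self):
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.cue_set_type not in CUE_SET_TYPES:
            raise ValueError(f"unknown cue set type {self.cue_set_type!r}")
        if self.cue_set_size < 2:
            raise ValueError("cue_set_size must be >= 2")
        if self.responses_per_cue < 1:
            raise ValueError("responses_per_cue must be >= 1")

    @property
    def label(self) -> str:
        return (
            f"{self.paradigm}/{self.cue_set_type}"
            f"/size{self.cue_set_size}/resp{self.responses_per_cue}"
        )


def _rng_choice(rng: np.random.Generator, items: list[str]) -> str:
    return items[rng.integers(len(items))]


def _grow_narrow(
    net: SemanticNetwork,
    included: list[str],
    n_add: int,
    rng: np.random.Generator,
    exclude: set[str],
) -> list[str]:
    """Greedily add `n_add` nodes with the highest average edge weight to `included`.

    The average is taken over existing edges to included nodes only; ties are
    broken uniformly at random.  `exclude` nodes are never candidates.
    """
    added: list[str] = []
    members = set(included)
    for _ in range(n_add):
        candidates: dict[str, list[float]] = {}
        for node in included + added:
            for nbr in net.neighbors(node):
                if nbr in members or nbr in exclude:
                    continue
                candidates.setdefault(nbr, []).append(net.weight(node, nbr))
        if not candidates:
            raise ValueError(
                f"cue-set component exhausted: reached {len(included) + len(added)} nodes"
            )
        means = {c: float(np.mean(ws)) for c, ws in candidates.items()}
        best = max(means.values())
        tied = sorted(c for c, m in means.items() if m == best)
        pick = _rng_choice(rng, tied)
        added.append(pick)
        members.add(pick)
    return added


def narrow_cues(net: SemanticNetwork, size: int, seed: int, instantiation_id: int = 0) -> CueSet:
    """One tight neighborhood grown greedily from a uniformly drawn start node."""
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    start = _rng_choice(rng, list(net.nodes))
    cues = [start] + _grow_narrow(net, [start], size - 1, rng, exclude=set())
    return CueSet(tuple(cues), "narrow", seed, instantiation_id)


def _walk_broad(
    net: SemanticNetwork,
    n_nodes: int,
    rng: np.random.Generator,
    exclude: set[str],
) -> list[str]:
    eligible = [n for n in net.nodes if n not in exclude]
    if not eligible:
        raise ValueError("no eligible start node")
    current = _rng_choice(rng, eligible)
    cues = [current]
    members = {current}
    while len(cues) < n_nodes:
        fresh = [n for n in net.neighbors(current) if n not in members and n not in exclude]
        if not fresh:
            # dead end: restart from an included node that still has unvisited
            # neighbors (restarting blindly could loop forever)
            restartable = [
                c
                for c in cues
                if any(n not in members and n not in exclude for n in net.neighbors(c))
            ]
            if not restartable:
                raise ValueError(f"cue-set component exhausted: reached {len(cues)} nodes")
            current = _rng_choice(rng, sorted(restartable))
            continue
        current = _rng_choice(rng, sorted(fresh))
        cues.append(current)
        members.add(current)
    return cues


def broad_cues(net: SemanticNetwork, size: int, seed: int, instantiation_id: int = 0) -> CueSet:
    """A random walk over unvisited neighbors, covering the network widely."""
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    cues = _walk_broad(net, size, rng, exclude=set())
    return CueSet(tuple(cues), "broad", seed, instantiation_id)


def mixed_cues(net: SemanticNetwork, size: int, seed: int, instantiation_id: int = 0) -> CueSet:
    """floor(sqrt(size)) broad seeds, each grown into a narrow neighborhood.

    The remaining size - n_b cues are split into n_b batches (as equal as
    possible, remainder to the earliest seeds); batch b is grown narrowly from
    broad seed b, excluding all cues chosen so far.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    n_b = int(math.isqrt(size))
    seeds = _walk_broad(net, n_b, rng, exclude=set())
    remaining = size - n_b
    base, extra = divmod(remaining, n_b)
    batch_sizes = [base + (1 if b < extra else 0) for b in range(n_b)]
    cues = list(seeds)
    chosen = set(cues)
    for seed_node, batch in zip(seeds, batch_sizes):
        grown = _grow_narrow(net, [seed_node], batch, rng, exclude=chosen - {seed_node})
        cues.extend(grown)
        chosen.update(grown)
    return CueSet(tuple(cues), "mixed", seed, instantiation_id)


_GENERATORS = {"narrow": narrow_cues, "broad": broad_cues, "mixed": mixed_cues}


def generate_cues(
    net: SemanticNetwork, cue_set_type: str, size: int, seed: int, instantiation_id: int = 0
) -> CueSet:
    """Dispatch to the narrow/broad/mixed generator by name."""
    try:
        gen = _GENERATORS[cue_set_type]
    except KeyError:
        raise ValueError(f"unknown cue set type {cue_set_type!r}") from None
    return gen(net, size, seed, instantiation_id)


def enumerate_designs(
    paradigms=PARADIGMS,
    cue_set_types=CUE_SET_TYPES,
    cue_set_sizes=(10, 100, 1000),
    responses_per_cue=(3, 30, 300),
    n_instantiations: int = 10,
    n_participants: int = 250,
    base_seed: int = 0,
) -> list[DesignConfig]:
    """Full Cartesian design grid in deterministic order."""
    for name, axis in [
        ("paradigms", paradigms),
        ("cue_set_types", cue_set_types),
        ("cue_set_sizes", cue_set_sizes),
        ("responses_per_cue", responses_per_cue),
    ]:
        if not axis:
            raise ValueError(f"empty design axis {name!r}")
    return [
        DesignConfig(
            paradigm=pa,
            cue_set_type=ct,
            cue_set_size=cs,
            responses_per_cue=nr,
            n_instantiations=n_instantiations,
            n_participants=n_participants,
            seed=base_seed + idx,
        )
        for idx, (pa, ct, cs, nr) in enumerate(
            itertools.product(paradigms, cue_set_types, cue_set_sizes, responses_per_cue)
        )
    ]


def paper_grid(base_seed: int = 0) -> list[DesignConfig]:
    """The full 54-cell study grid: 2 paradigms x 3 types x {10,100,1000} cues
    x {3,30,300} responses, 10 instantiations x 250 participants each."""
    return enumerate_designs(base_seed=base_seed)
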