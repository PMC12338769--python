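"""Behavioral-data simulation: free association and relatedness judgments.

Free associations follow a similarity-by-frequency retrieval rule.  For cue j,
the probability of producing neighbor i is

    P(i | j) ∝ w_ij^γw · f_i^γf

over the cue's network neighbors, where w_ij is the edge weight, f_i the
relative word frequency, and γw, γf sensitivity exponents (defaults 10 and 1,
the values that best reproduce large free-association norms).  Responses
within a trial are drawn without replacement with renormalization; sampling
resets across trials.

Relatedness judgments map an edge weight to a rating on a 1–20 scale through
a truncated normal:

    RJ(i, j) ~ TN(μ(w_ij), σ², 1, 20),   μ(w) = 1 + 19 · w^γ

with γ = 1 and σ = 3.85 by default (absent edges have w = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cues import CueSet
from .graph import SemanticNetwork
from .groundtruth import Lexicon

__all__ = [
    "FAParams",
    "RJParams",
    "BehavioralDataset",
    "fa_distribution",
    "simulate_fa",
    "simulate_rj",
    "sensitivity_grid_search",
]


@dataclass(frozen=True)
class FAParams:
    """Free-association retrieval parameters (defaults = tuned values)."""

    gamma_w: float = 10.0  # similarity sensitivity
    gamma_f: float = 1.0  # frequency sensitivity
    responses_per_trial: int = 3

    def __post_init__(self):
        if self.gamma_w < 0 or self.gamma_f < 0:
            raise ValueError("sensitivities must be >= 0")
        if self.responses_per_trial < 1:
            raise ValueError("responses_per_trial must be >= 1")


@dataclass(frozen=True)
class RJParams:
    """Relatedness-judgment parameters (defaults = tuned values).

    sigma is the truncated-normal standard deviation on the 1–20 rating
    scale; sigma = 0 gives deterministic ratings at the location μ(w).
    """

    gamma: float = 1.0
    sigma: float = 3.85
    scale_min: float = 1.0
    scale_max: float = 20.0
    round_ratings: bool = False

    def __post_init__(self):
        if self.gamma < 0 or self.sigma < 0:
            raise ValueError("gamma and sigma must be >= 0")
        if not self.scale_min < self.scale_max:
            raise ValueError("scale_min must be < scale_max")

    def location(self, w: float) -> float:
        """Rating-scale location μ(w): [0, 1] mapped affinely onto the scale."""
        span = self.scale_max - self.scale_min
        return self.scale_min + span * w**self.gamma


@dataclass
class BehavioralDataset:
    """Long-format simulated responses.

    FA records: participant, instantiation, cue, trial, position, response.
    RJ records: participant, instantiation, word_i, word_j, rating.
    """

    paradigm: str
    records: pd.DataFrame
    n_skipped_cues: int = 0

    def __len__(self) -> int:
        return len(self.records)


def fa_distribution(
    net: SemanticNetwork,
    cue: str,
    lex: Lexicon,
    params: FAParams = FAParams(),
    exclude: frozenset[str] | set[str] = frozenset(),
) -> pd.Series:
    """Exact response distribution P(i | cue) over eligible neighbors.

    Support = network neighbors of the cue minus `exclude` (the cue itself is
    never a neighbor).  Raises ``ValueError`` on empty support.
    """
    candidates = [n for n in net.neighbors(cue) if n not in exclude]
    if not candidates:
        raise ValueError(f"cue {cue!r} has no eligible neighbor")
    w = np.array([net.weight(cue, c) for c in candidates])
    f = np.array([lex[c] for c in candidates])
    scores = w**params.gamma_w * f**params.gamma_f
    total = scores.sum()
    if total <= 0:
        raise ValueError(f"cue {cue!r}: all response scores are zero")
    return pd.Series(scores / total, index=candidates)


def simulate_fa(
    net: SemanticNetwork,
    cueset: CueSet,
    n_responses: int,
    lex: Lexicon,
    params: FAParams = FAParams(),
    seed: int = 0,
    participant_id: int = 0,
) -> BehavioralDataset:
    """Simulate `n_responses` free associations per cue.

    Responses come in trials of ``params.responses_per_trial`` (a final
    shorter trial is allowed); within a trial sampling is without replacement
    with renormalization, across trials it resets.  Cues with no neighbors in
    the individual's network are skipped and counted.
    """
    if n_responses < 1:
        raise ValueError("n_responses must be >= 1")
    rng = np.random.default_rng(seed)
    rpt = params.responses_per_trial
    rows = []
    n_skipped = 0
    for cue in cueset.cues:
        candidates = net.neighbors(cue) if cue in net else ()
        if not candidates:
            n_skipped += 1
            continue
        # unnormalized retrieval scores, computed once per cue; within-trial
        # removal + renormalization is done by masking (same math as
        # fa_distribution with a growing exclude set)
        w = np.array([net.weight(cue, c) for c in candidates])
        f = np.array([lex[c] for c in candidates])
        base = w**params.gamma_w * f**params.gamma_f
        if base.sum() <= 0:
            n_skipped += 1
            continue
        remaining = n_responses
        trial = 0
        while remaining > 0:
            trial += 1
            n_here = min(rpt, remaining)
            remaining -= n_here
            scores = base.copy()
            for position in range(1, n_here + 1):
                total = scores.sum()
                if total <= 0:
                    break  # support exhausted mid-trial
                idx = rng.choice(len(candidates), p=scores / total)
                rows.append(
                    (
                        participant_id,
                        cueset.instantiation_id,
                        cue,
                        trial,
                        position,
                        candidates[idx],
                    )
                )
                scores[idx] = 0.0
    df = pd.DataFrame(
        rows,
        columns=["participant", "instantiation", "cue", "trial", "position", "response"],
    )
    return BehavioralDataset("free_association", df, n_skipped)


def _allocate_pairs(
    pairs: list[tuple[str, str]], budget: int, rng: np.random.Generator
) -> np.ndarray:
    """Number of ratings per pair: floor division plus one extra for a random
    subset when the budget exceeds the pair count, else `budget` random pairs
    rated once."""
    n_pairs = len(pairs)
    counts = np.zeros(n_pairs, dtype=int)
    if budget >= n_pairs:
        counts += budget // n_pairs
        extra = budget % n_pairs
        if extra:
            counts[rng.choice(n_pairs, size=extra, replace=False)] += 1
    else:
        counts[rng.choice(n_pairs, size=budget, replace=False)] = 1
    return counts


def simulate_rj(
    net: SemanticNetwork,
    cueset: CueSet,
    n_responses: int,
    params: RJParams = RJParams(),
    seed: int = 0,
    participant_id: int = 0,
) -> BehavioralDataset:
    """Simulate relatedness ratings for the cue set's word pairs.

    The judgment budget |cues| × n_responses is spread over the
    |cues|·(|cues|−1)/2 unordered pairs (see :func:`_allocate_pairs`); each
    rating is a truncated-normal draw around μ(w_ij) via inverse-CDF sampling
    for exact seed reproducibility.
    """
    if len(cueset) < 2:
        raise ValueError("relatedness judgments need at least 2 cues")
    rng = np.random.default_rng(seed)
    pairs = [tuple(sorted(p)) for p in combinations(cueset.cues, 2)]
    counts = _allocate_pairs(pairs, len(cueset) * n_responses, rng)

    lo, hi = params.scale_min, params.scale_max
    rows = []
    for (wi, wj), n_ratings in zip(pairs, counts):
        if n_ratings == 0:
            continue
        mu = params.location(net.weight(wi, wj))
        if params.sigma == 0.0:
            ratings = np.full(n_ratings, min(max(mu, lo), hi))
        else:
            u = rng.uniform(size=n_ratings)
            a, b = (lo - mu) / params.sigma, (hi - mu) / params.sigma
            ratings = truncnorm.ppf(u, a, b, loc=mu, scale=params.sigma)
            ratings = np.clip(ratings, lo, hi)  # guard ppf endpoint roundoff
        if params.round_ratings:
            ratings = np.clip(np.round(ratings), lo, hi)
        for rating in ratings:
            rows.append((participant_id, cueset.instantiation_id, wi, wj, float(rating)))
    df = pd.DataFrame(
        rows, columns=["participant", "instantiation", "word_i", "word_j", "rating"]
    )
    return BehavioralDataset("relatedness_judgment", df)


def sensitivity_grid_search(
    simulator,
    reference: pd.Series,
    grid: dict[str, list],
    metric: str = "pearson",
) -> tuple[dict, pd.DataFrame]:
    """Generic tuning of sensitivity parameters against a reference distribution.

    `simulator` maps keyword parameters (one per grid axis) to a pd.Series on
    (a superset of) the reference's support — e.g. a first-response
    distribution for free association or a vector of mean ratings for
    relatedness judgments.  Returns the argmax parameter dict and the full
    correlation surface as a DataFrame with one row per grid point.
    """
    from scipy.stats import pearsonr, spearmanr

    if metric not in ("pearson", "spearman"):
        raise ValueError(f"unknown metric {metric!r}")
    if reference.nunique() <= 1:
        raise ValueError("reference distribution is constant: correlation undefined")
    corr = pearsonr if metric == "pearson" else spearmanr

    names = list(grid)
    import itertools as it

    rows = []
    best_score, best_params = -np.inf, None
    for values in it.product(*(grid[n] for n in names)):
        params = dict(zip(names, values))
        sim = simulator(**params)
        aligned = sim.reindex(reference.index).fillna(0.0)
        if aligned.nunique() <= 1:
            score = float("nan")
        else:
            score = float(corr(aligned.to_numpy(), reference.to_numpy())[0])
        rows.append({**params, "score": score})
        if not math.isnan(score) and score > best_score:
            best_score, best_params = score, params
    surface = pd.DataFrame(rows)
    if best_params is None:
        raise ValueError("no grid point produced a defined correlation")
    return best_params, surface
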