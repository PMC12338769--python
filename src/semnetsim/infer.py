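"""Network inference from simulated behavior.

Free association: build the cue × response count matrix, transform counts to
positive pointwise mutual information (PPMI, base-2 log, negatives clamped to
zero), and connect cues by the cosine similarity of their transformed
response distributions.  Relatedness judgment: average the ratings per word
pair and rescale the 1–20 scale affinely to [0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import cosine_similarity

from .behavior import BehavioralDataset
from .cues import CueSet
from .graph import SemanticNetwork

__all__ = ["cue_response_matrix", "ppmi_transform", "fa_infer", "rj_infer"]

logger = logging.getLogger(__name__)


def cue_response_matrix(data: BehavioralDataset, cueset: CueSet) -> pd.DataFrame:
    """Cue × response count matrix.

    Rows follow the cue-set order; columns are all words observed as responses
    in the dataset, lexicographically ordered.  Cues that never occur in the
    data get all-zero rows (logged as a warning).
    """
    if data.paradigm != "free_association":
        raise ValueError("cue_response_matrix requires free-association data")
    rec = data.records
    vocab = sorted(rec["response"].unique()) if len(rec) else []
    counts = pd.DataFrame(0, index=list(cueset.cues), columns=vocab, dtype=float)
    if len(rec):
        tab = rec.groupby(["cue", "response"]).size()
        for (cue, resp), n in tab.items():
            if cue in counts.index:
                counts.loc[cue, resp] = n
    observed_cues = set(rec["cue"]) if len(rec) else set()
    absent = [c for c in cueset.cues if c not in observed_cues]
    if absent:
        logger.warning("%d cue(s) absent from FA data, treated as all-zero rows", len(absent))
    return counts


def ppmi_transform(m) -> pd.DataFrame | np.ndarray:
    """Positive pointwise mutual information of a count matrix.

    cell(c, r) = max(0, log2( p(c,r) / (p(c) p(r)) )) with maximum-likelihood
    probabilities from the matrix totals; zero counts stay 0.
    """
    values = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero count matrix")
    p = values / total
    p_row = p.sum(axis=1, keepdims=True)
    p_col = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log2(p / (p_row * p_col))
    ppmi = np.where((p > 0) & (pmi > 0), pmi, 0.0)
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(ppmi, index=m.index, columns=m.columns)
    return ppmi


def fa_infer(data: BehavioralDataset, cueset: CueSet, use_ppmi: bool = True) -> SemanticNetwork:
    """Cosine-similarity network over (PPMI-transformed) response distributions.

    Nodes are the cues; an edge carries the cosine of the two cues' rows.
    All-zero rows (cues without data) yield similarity 0, leaving the cue as
    an isolated node so node sets stay comparable across individuals.
    """
    counts = cue_response_matrix(data, cueset)
    x = ppmi_transform(counts).to_numpy() if use_ppmi else counts.to_numpy()
    net = SemanticNetwork(cueset.cues, meta="inferred-FA")
    if x.shape[1] == 0:
        return net
    sims = cosine_similarity(x)
    cues = list(cueset.cues)
    for a in range(len(cues)):
        for b in range(a + 1, len(cues)):
            w = min(float(sims[a, b]), 1.0)
            if w > 0.0:
                net.add_edge(cues[a], cues[b], w)
    return net


def rj_infer(data: BehavioralDataset, cueset: CueSet, scale_min: float = 1.0, scale_max: float = 20.0) -> SemanticNetwork:
    """Average ratings per pair, rescaled from [scale_min, scale_max] to [0, 1].

    Unjudged pairs stay absent (weight 0); a judged pair averaging to the
    scale minimum also maps to weight 0 (absent edge).
    """
    if data.paradigm != "relatedness_judgment":
        raise ValueError("rj_infer requires relatedness-judgment data")
    rec = data.records
    if len(rec):
        bad = rec[(rec["rating"] < scale_min - 1e-9) | (rec["rating"] > scale_max + 1e-9)]
        if len(bad):
            raise ValueError(
                f"{len(bad)} rating(s) outside [{scale_min}, {scale_max}], e.g. {bad['rating'].iloc[0]}"
            )
    net = SemanticNetwork(cueset.cues, meta="inferred-RJ")
    if not len(rec):
        return net
    span = scale_max - scale_min
    means = rec.groupby(["word_i", "word_j"])["rating"].mean()
    for (wi, wj), mean_rating in means.items():
        w = min(max((mean_rating - scale_min) / span, 0.0), 1.0)
        if w > 0.0:
            net.add_edge(wi, wj, w)
    return net
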