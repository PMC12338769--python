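"""Common ground-truth network construction and word frequencies.

The common ground truth is a cosine-similarity network over word-embedding
vectors, thresholded at a minimum edge weight (default 0.2).  By default the
embeddings are synthetic — a clustered unit-vector model that emulates the
community structure of real distributional embeddings — so the whole pipeline
runs without any external download.  Real embeddings in word2vec/fastText text
format and a word-frequency table can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import cosine_similarity

from .graph import SemanticNetwork

__all__ = [
    "EmbeddingTable",
    "Lexicon",
    "cosine_network",
    "synth_embeddings",
    "synth_frequencies",
    "load_embeddings",
    "load_frequencies",
    "DEFAULT_CUTOFF",
]

#: minimum edge weight of ground-truth networks
DEFAULT_CUTOFF = 0.2


@dataclass(frozen=True)
class EmbeddingTable:
    """Fixed-dimension real vectors keyed by word, in a stable word order."""

    words: tuple[str, ...]
    vectors: np.ndarray  # shape (n_words, dim)

    def __post_init__(self):
        if self.vectors.ndim != 2 or len(self.words) != self.vectors.shape[0]:
            raise ValueError("vectors must be a (n_words, dim) array matching words")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(norms == 0):
            bad = self.words[int(np.argmin(norms))]
            raise ValueError(f"zero-norm embedding vector for word {bad!r}")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.words)


class Lexicon(dict):
    """Mapping word → relative frequency f_i, normalized to sum 1."""

    def __init__(self, frequencies: dict[str, float]):
        freqs = {str(w): float(f) for w, f in frequencies.items()}
        if not freqs:
            raise ValueError("empty lexicon")
        if any(f <= 0 for f in freqs.values()):
            raise ValueError("all frequencies must be strictly positive")
        total = sum(freqs.values())
        super().__init__({w: f / total for w, f in freqs.items()})

    def frequency(self, word: str) -> float:
        return self[word]


def cosine_network(emb: EmbeddingTable, cutoff: float = DEFAULT_CUTOFF) -> SemanticNetwork:
    """Thresholded cosine-similarity network over embedding vectors.

    An edge (i, j) is present iff cosine(v_i, v_j) >= cutoff, weighted by the
    cosine value.  Negative cosines never produce edges (cutoff is
    non-negative).
    """
    if len(emb) < 2:
        raise ValueError("need at least 2 words")
    if not (0.0 <= cutoff < 1.0):
        raise ValueError(f"cutoff must be in [0, 1), got {cutoff}")
    sims = cosine_similarity(emb.vectors)
    net = SemanticNetwork(emb.words, meta="ground-truth")
    n = len(emb)
    ii, jj = np.triu_indices(n, k=1)
    keep = sims[ii, jj] >= cutoff
    for a, b in zip(ii[keep], jj[keep]):
        w = min(float(sims[a, b]), 1.0)  # guard FP overshoot on identical vectors
        if w > 0:
            net.add_edge(emb.words[a], emb.words[b], w)
    return net


def synth_embeddings(
    n_words: int = 300,
    dim: int = 16,
    n_communities: int = 6,
    within_noise: float = 0.35,
    seed: int = 0,
) -> EmbeddingTable:
    """Clustered synthetic embeddings emulating topical structure.

    Words are assigned round-robin to `n_communities` communities; each word's
    vector is the unit-normalized sum of its community's random unit center and
    isotropic Gaussian noise of scale `within_noise`.  Smaller noise gives
    tighter communities (same-community cosines → 1 as noise → 0).
    """
    if n_communities < 1 or n_words < n_communities:
        raise ValueError("need n_words >= n_communities >= 1")
    if dim < 2:
        raise ValueError("need dim >= 2")
    if within_noise <= 0:
        raise ValueError("within_noise must be > 0")
    rng = np.random.default_rng(seed)
    centers = rng.normal(size=(n_communities, dim))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    width = len(str(n_words - 1))
    words = tuple(f"w{k:0{width}d}" for k in range(n_words))
    comm = np.arange(n_words) % n_communities
    vecs = centers[comm] + within_noise * rng.normal(size=(n_words, dim))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return EmbeddingTable(words, vecs)


def synth_frequencies(n_words: int, zipf_exponent: float = 1.0, seed: int = 0) -> Lexicon:
    """Zipfian word frequencies randomly assigned to synthetic words.

    The rank-k frequency is proportional to k^(-zipf_exponent); exponent 0
    gives a uniform lexicon.  Word names match :func:`synth_embeddings`.
    """
    if n_words < 1:
        raise ValueError("need n_words >= 1")
    if zipf_exponent < 0:
        raise ValueError("zipf_exponent must be >= 0")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, n_words + 1, dtype=float)
    freqs = ranks**-zipf_exponent
    rng.shuffle(freqs)
    width = len(str(n_words - 1))
    return Lexicon({f"w{k:0{width}d}": freqs[k] for k in range(n_words)})


def load_embeddings(path, vocabulary=None) -> tuple[EmbeddingTable, list[str]]:
    """Read word2vec/fastText text format, optionally restricted to a vocabulary.

    The format is a header line ``n d`` followed by ``word v1 ... vd`` lines.
    Returns the table and the sorted list of requested words that were absent.
    """
    wanted = None if vocabulary is None else {str(w) for w in vocabulary}
    words: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"malformed header line in {path}: expected 'n d'")
        _, dim = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            word, values = parts[0], parts[1:]
            if values and values[-1] == "":
                values = values[:-1]
            if len(values) != dim:
                raise ValueError(
                    f"{path}:{lineno}: expected {dim} values for {word!r}, got {len(values)}"
                )
            if wanted is not None and word not in wanted:
                continue
            try:
                vec = np.array([float(v) for v in values])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric value for {word!r}") from err
            words.append(word)
            rows.append(vec)
    missing = sorted(wanted - set(words)) if wanted is not None else []
    if not words:
        raise ValueError(f"no requested words found in {path}")
    return EmbeddingTable(tuple(words), np.vstack(rows)), missing


def load_frequencies(path) -> Lexicon:
    """Read a two-column CSV ``word,count_or_frequency`` into a Lexicon."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"frequency table {path} needs two columns (word, count)")
    word_col, freq_col = df.columns[:2]
    return Lexicon(dict(zip(df[word_col].astype(str), df[freq_col].astype(float))))
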