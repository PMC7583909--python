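"""Sequence-intrinsic feature encoders: k-mer spectrum and CTD descriptor.

Both encoders are pure functions of the nucleotide string. Each RNA is also
decomposed into three reading-frame sub-sequences (the suffixes starting at
positions 0, 1 and 2); every feature category is computed once per phase and
the per-phase vectors are what the histogram fusion consumes.

Dimensionalities follow the method's contract: the k-mer spectrum uses
k = 1..4 for lncRNAs (4 + 16 + 64 + 256 = 340 dims) and k = 1..3 for miRNAs
(84 dims, since 4-mers are too sparse in a ~22 nt sequence); the CTD
(composition / transition / distribution) descriptor is always 30 dims.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io import RNARecord

__all__ = [
    "phase_subsequences",
    "kmer_vector",
    "ctd_vector",
    "tokenize_3mers",
    "KmerEncoder",
    "CTDEncoder",
    "FeatureBundle",
    "KS_LNC",
    "KS_MIR",
    "CTD_DIM",
]

#: k values per RNA kind (ascending); lncRNA 340 dims, miRNA 84 dims.
KS_LNC: tuple[int, ...] = (1, 2, 3, 4)
KS_MIR: tuple[int, ...] = (1, 2, 3)
CTD_DIM = 30

#: Nucleotide order used by the CTD composition and distribution blocks.
CTD_NUCLEOTIDES = "ATGC"
#: Unordered adjacent-pair order of the CTD transition block.
CTD_PAIRS = (("A", "T"), ("A", "C"), ("A", "G"), ("T", "G"), ("T", "C"), ("G", "C"))

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def phase_subsequences(seq: str) -> tuple[str, str, str]:
    """Decompose a sequence into its three reading-frame suffixes.

    Returns ``(seq, seq[1:], seq[2:])`` — the sub-sequences starting at
    positions 0, 1 and 2. Requires length >= 3 so every phase is non-empty.
    """
    if len(seq) < 3:
        raise ValueError(f"sequence too short for phase decomposition: {len(seq)} < 3")
    return seq, seq[1:], seq[2:]


def _kmer_indices(seq: str, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers (A<C<G<T lexicographic)."""
    codes = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    idx = np.zeros(len(seq) - k + 1, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + codes[j : len(seq) - k + 1 + j]
    return idx


def kmer_vector(seq: str, ks: Sequence[int] = KS_LNC) -> np.ndarray:
    """Concatenated k-mer frequency spectrum.

    For each k (ascending) the block holds the 4^k overlapping-window
    frequencies, i.e. counts divided by the number of windows L - k + 1,
    in lexicographic mer order with A < C < G < T. Each block sums to 1.
    """
    ks = sorted(set(ks))
    if not ks:
        raise ValueError("ks must be non-empty")
    if len(seq) < max(ks):
        raise ValueError(f"sequence of length {len(seq)} shorter than k={max(ks)}")
    blocks = []
    for k in ks:
        counts = np.bincount(_kmer_indices(seq, k), minlength=4**k).astype(float)
        blocks.append(counts / (len(seq) - k + 1))
    return np.concatenate(blocks)


def ctd_vector(seq: str) -> np.ndarray:
    """30-dim composition / transition / distribution descriptor.

    Layout (all components in [0, 1]):

    * composition (4): count(x)/L for x in A, T, G, C;
    * transition (6): for unordered adjacent pairs AT, AC, AG, TG, TC, GC,
      the number of adjacent positions whose two (distinct) nucleotides form
      that pair, in either orientation, divided by L - 1;
    * distribution (20): for x in A, T, G, C, the 1-based positions of the
      first, 25%, 50%, 75% and last occurrence (occurrence ranks 1,
      ceil(q*n) for q = .25, .5, .75, and n) divided by L. A nucleotide
      absent from the sequence contributes five zeros.
    """
    L = len(seq)
    if L < 2:
        raise ValueError("CTD requires length >= 2 (transition undefined)")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters for CTD: {sorted(bad)}")

    comp = np.array([seq.count(x) / L for x in CTD_NUCLEOTIDES])

    pair_counts = dict.fromkeys(frozenset(p) for p in CTD_PAIRS)
    for key in pair_counts:
        pair_counts[key] = 0
    for a, b in zip(seq, seq[1:]):
        if a != b:
            pair_counts[frozenset((a, b))] += 1
    trans = np.array([pair_counts[frozenset(p)] / (L - 1) for p in CTD_PAIRS])

    dist = np.zeros(20)
    for xi, x in enumerate(CTD_NUCLEOTIDES):
        positions = [i + 1 for i, c in enumerate(seq) if c == x]
        n = len(positions)
        if n == 0:
            continue
        ranks = [1] + [int(np.ceil(q * n)) for q in (0.25, 0.5, 0.75)] + [n]
        dist[5 * xi : 5 * xi + 5] = [positions[r - 1] / L for r in ranks]

    return np.concatenate([comp, trans, dist])


def tokenize_3mers(seq: str) -> list[str]:
    """Overlapping 3-mer tokens (window step 1), the sentence form of an RNA."""
    if len(seq) < 3:
        raise ValueError(f"sequence of length {len(seq)} too short to tokenize")
    return [seq[i : i + 3] for i in range(len(seq) - 2)]


@dataclass
class FeatureBundle:
    """Per-RNA container of per-phase, per-category feature vectors.

    ``vectors[(phase, category)]`` holds a 1-D float array. Phases are 0, 1, 2
    (reading-frame suffixes); categories are "kmer", "ctd", "doc2vec" and
    "graph". The graph embedding has no phase structure, so the single node
    vector is stored under all three phases.
    """

    rna_id: str
    kind: str
    vectors: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    CATEGORIES = ("kmer", "ctd", "doc2vec", "graph")

    def get(self, phase: int, category: str) -> np.ndarray:
        try:
            return self.vectors[(phase, category)]
        except KeyError:
            raise KeyError(
                f"bundle {self.rna_id!r} lacks category {category!r} for phase {phase}"
            ) from None

    def categories(self) -> tuple[str, ...]:
        return tuple(
            c for c in self.CATEGORIES if any((p, c) in self.vectors for p in range(3))
        )


def _as_sequences(X: Iterable) -> list[str]:
    out = []
    for x in X:
        out.append(x.seq if isinstance(x, RNARecord) else str(x))
    return out


class KmerEncoder(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping sequences to k-mer frequency spectra.

    Parameters
    ----------
    ks : tuple of int
        k values to concatenate (ascending); (1,2,3,4) for lncRNAs,
        (1,2,3) for miRNAs.
    """

    def __init__(self, ks: tuple[int, ...] = KS_LNC):
        self.ks = ks

    def fit(self, X, y=None):
        self.n_features_out_ = int(sum(4**k for k in self.ks))
        return self

    def transform(self, X) -> np.ndarray:
        return np.array([kmer_vector(s, self.ks) for s in _as_sequences(X)])


class CTDEncoder(TransformerMixin, BaseEstimator):
    """Stateless transformer mapping sequences to 30-dim CTD descriptors."""

    def fit(self, X, y=None):
        self.n_features_out_ = CTD_DIM
        return self

    def transform(self, X) -> np.ndarray:
        return np.array([ctd_vector(s) for s in _as_sequences(X)])
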