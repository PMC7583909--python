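"""Document-style RNA sequence embedding via PV-DM paragraph vectors.

An RNA sequence is treated as a sentence of overlapping 3-mer tokens and
embedded with a distributed-memory paragraph-vector model (PV-DM): a center
token is predicted from the average of the paragraph vector and context
token vectors through an exact softmax over the 64-token 3-mer vocabulary.
lncRNAs and miRNAs get
separate embedders (128 and 64 dimensions respectively), trained on the
corpus of the RNAs at hand; new sequences are embedded by inference with
word vectors frozen.

The token vocabulary is the full set of 64 possible 3-mers in lexicographic
order, so inference never meets an out-of-vocabulary token.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._sgns import PVDM
from .features import tokenize_3mers
from .io import RNARecord

__all__ = ["Doc2VecEncoder", "train_doc_embedder", "infer_doc_vector", "VOCAB_3MERS"]

VOCAB_3MERS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)
_TOKEN_INDEX = {t: i for i, t in enumerate(VOCAB_3MERS)}


def _encode_tokens(tokens: Sequence[str]) -> np.ndarray:
    try:
        return np.array([_TOKEN_INDEX[t] for t in tokens], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"invalid 3-mer token {e.args[0]!r}") from None


def _as_token_lists(X: Iterable) -> list[list[str]]:
    docs = []
    for x in X:
        if isinstance(x, RNARecord):
            docs.append(tokenize_3mers(x.seq))
        elif isinstance(x, str):
            docs.append(tokenize_3mers(x))
        else:  # already a token list
            docs.append(list(x))
    return docs


class Doc2VecEncoder(TransformerMixin, BaseEstimator):
    """PV-DM sequence embedder with the sklearn transformer interface.

    Parameters
    ----------
    dim : int
        Embedding dimensionality (128 for lncRNAs, 64 for miRNAs).
    window : int
        Symmetric context window, in tokens.
    epochs : int
        Training (and inference) epochs.
    seed : int
        Seed controlling vector initialization; training is
        reproducible bit-for-bit for a fixed seed (single worker).

    Attributes
    ----------
    model_ : PVDM
        The trained paragraph-vector model.
    """

    def __init__(self, dim: int = 128, window: int = 5, epochs: int = 40, seed: int = 0):
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.seed = seed

    def fit(self, X, y=None):
        docs = _as_token_lists(X)
        if not docs:
            raise ValueError("empty corpus")
        encoded = [_encode_tokens(d) for d in docs]
        self.model_ = PVDM(
            dim=self.dim,
            window=self.window,
            epochs=self.epochs,
            seed=self.seed,
        ).fit(encoded, vocab_size=len(VOCAB_3MERS))
        return self

    def transform(self, X) -> np.ndarray:
        """Infer a fixed-size vector for each sequence / token list."""
        if not hasattr(self, "model_"):
            raise RuntimeError("Doc2VecEncoder is not fitted")
        return np.array(
            [self.model_.infer(_encode_tokens(d)) for d in _as_token_lists(X)]
        )


def train_doc_embedder(corpus: list[list[str]], dim: int, seed: int, **kw) -> Doc2VecEncoder:
    """Train a PV-DM embedder on a corpus of 3-mer token lists."""
    return Doc2VecEncoder(dim=dim, seed=seed, **kw).fit(corpus)


def infer_doc_vector(embedder: Doc2VecEncoder, seq: str) -> np.ndarray:
    """Infer the embedding of one nucleotide sequence (tokenized to 3-mers)."""
    return embedder.transform([seq])[0]
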