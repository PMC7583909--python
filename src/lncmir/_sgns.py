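"""Shallow embedding trainers (skip-gram and PV-DM), in numpy.

Machinery for the two embedding models the package needs: a
distributed-memory paragraph-vector model (PV-DM) for document-style RNA
sequence embeddings, and a skip-gram model over random-walk role sequences
for node embeddings.

Both vocabularies are tiny by construction (64 possible 3-mers; a bounded
set of node roles), so the softmax over the vocabulary is computed exactly
instead of being approximated by negative sampling: gradients reduce to a
handful of dense matmuls per document, which keeps training fast and
bit-reproducible for a fixed seed. The skip-gram trainer goes one step
further and trains full-batch on the (center role, context role)
co-occurrence counts, which is the same objective with the sum over
identical pairs collapsed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SkipGramSoftmax", "PVDM"]


def _softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _init_vectors(n: int, dim: int, rng: np.random.Generator) -> np.ndarray:
    # word2vec-style init: uniform in [-0.5/dim, 0.5/dim)
    return (rng.random((n, dim)) - 0.5) / dim


def _windowed_sum(rows: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """For each position i: sum and count of rows j with 0 < |i-j| <= window."""
    L = len(rows)
    csum = np.cumsum(rows, axis=0)
    pad = np.vstack([np.zeros((1, rows.shape[1])), csum])  # pad[i] = sum rows[:i]
    lo = np.maximum(np.arange(L) - window, 0)
    hi = np.minimum(np.arange(L) + window, L - 1)
    return pad[hi + 1] - pad[lo] - rows, (hi - lo).astype(float)


class SkipGramSoftmax:
    """Full-softmax skip-gram over integer-token sentences with a small vocabulary.

    Training is full-batch on the co-occurrence count matrix ``C[c, o]`` of
    (center, context) pairs within the window, minimizing the mean
    cross-entropy ``-sum C[c,o] log softmax(W_in[c] . W_out)[o] / sum C``
    by gradient descent with a linearly decaying learning rate.

    Parameters
    ----------
    dim : int
        Embedding dimensionality.
    window : int
        Symmetric context window size.
    epochs : int
        Full-batch gradient steps.
    alpha, min_alpha : float
        Initial and final learning rate.
    seed : int
        Seed for vector initialization.
    """

    def __init__(
        self,
        dim: int = 128,
        window: int = 5,
        epochs: int = 200,
        alpha: float = 0.5,
        min_alpha: float = 0.01,
        seed: int = 0,
    ):
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.seed = seed

    def fit(self, sentences: list[np.ndarray], vocab_size: int) -> "SkipGramSoftmax":
        rng = np.random.Generator(np.random.PCG64(self.seed))
        self.W_in_ = _init_vectors(vocab_size, self.dim, rng)
        self.W_out_ = _init_vectors(vocab_size, self.dim, rng)

        C = np.zeros((vocab_size, vocab_size))
        for s in sentences:
            ids = np.asarray(s, dtype=np.int64)
            for off in range(1, min(self.window, len(ids) - 1) + 1):
                np.add.at(C, (ids[:-off], ids[off:]), 1.0)
                np.add.at(C, (ids[off:], ids[:-off]), 1.0)
        total = C.sum()
        if total == 0:
            return self  # no co-occurrences (all sentences length < 2)

        n_center = C.sum(axis=1)
        for epoch in range(self.epochs):
            lr = self.alpha + (self.min_alpha - self.alpha) * epoch / max(self.epochs, 1)
            P = _softmax(self.W_in_ @ self.W_out_.T)
            G = (P * n_center[:, None] - C) / total
            g_in = G @ self.W_out_
            g_out = G.T @ self.W_in_
            self.W_in_ -= lr * g_in
            self.W_out_ -= lr * g_out
        return self


class PVDM:
    """Distributed-memory paragraph vectors (PV-DM) with an exact softmax.

    Each document owns a trainable paragraph vector; a center token is
    predicted from the average of the paragraph vector and the in-window
    context token vectors. The softmax over the 64-token 3-mer vocabulary is
    computed exactly; updates are applied per document (full-batch over the
    document's positions). After training, unseen documents are embedded by
    the same gradient steps on a fresh paragraph vector with token vectors
    frozen.
    """

    def __init__(
        self,
        dim: int = 128,
        window: int = 5,
        epochs: int = 40,
        alpha: float = 0.25,
        min_alpha: float = 0.01,
        seed: int = 0,
    ):
        self.dim = dim
        self.window = window
        self.epochs = epochs
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _doc_grads(
        self, ids: np.ndarray, doc_vec: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-document mean-CE gradients: (token grad rows, W_out grad, doc grad)."""
        L = len(ids)
        rows = self.W_in_[ids]
        ctx_sum, n_ctx = _windowed_sum(rows, self.window)
        denom = (n_ctx + 1.0)[:, None]
        h = (ctx_sum + doc_vec) / denom

        P = _softmax(h @ self.W_out_.T)  # (L, V)
        P[np.arange(L), ids] -= 1.0
        P /= L
        g_out = P.T @ h
        gh = (P @ self.W_out_) / denom  # gradient reaching each contributor
        g_ctx, _ = _windowed_sum(gh, self.window)  # what each position's token receives
        return g_ctx, g_out, gh.sum(axis=0)

    def _step_document(
        self, ids: np.ndarray, doc_vec: np.ndarray, lr: float, update_words: bool
    ) -> None:
        if len(ids) < 2:
            return
        g_ctx, g_out, g_doc = self._doc_grads(ids, doc_vec)
        if update_words:
            np.add.at(self.W_in_, ids, -lr * g_ctx)
            self.W_out_ -= lr * g_out
        doc_vec -= lr * g_doc

    # -- public API --------------------------------------------------------

    def fit(self, documents: list[np.ndarray], vocab_size: int) -> "PVDM":
        """Train token, output and per-document paragraph vectors."""
        if not documents:
            raise ValueError("empty corpus")
        rng = np.random.Generator(np.random.PCG64(self.seed))
        self.vocab_size_ = vocab_size
        self.W_in_ = _init_vectors(vocab_size, self.dim, rng)
        self.W_out_ = _init_vectors(vocab_size, self.dim, rng)
        self.doc_vectors_ = _init_vectors(len(documents), self.dim, rng)

        docs = [np.asarray(d, dtype=np.int64) for d in documents]
        for epoch in range(self.epochs):
            lr = self.alpha + (self.min_alpha - self.alpha) * epoch / max(self.epochs, 1)
            for di, ids in enumerate(docs):
                self._step_document(ids, self.doc_vectors_[di], lr, update_words=True)
        return self

    def infer(
        self, ids: np.ndarray, epochs: int | None = None, seed: int | None = None
    ) -> np.ndarray:
        """Embed an unseen document with token/output vectors frozen."""
        if not hasattr(self, "W_in_"):
            raise RuntimeError("PVDM model is not trained")
        epochs = self.epochs if epochs is None else epochs
        rng = np.random.Generator(np.random.PCG64(self.seed + 1 if seed is None else seed))
        ids = np.asarray(ids, dtype=np.int64)
        vec = _init_vectors(1, self.dim, rng)[0]
        for epoch in range(epochs):
            lr = self.alpha + (self.min_alpha - self.alpha) * epoch / max(epochs, 1)
            self._step_document(ids, vec, lr, update_words=False)
        return vec
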