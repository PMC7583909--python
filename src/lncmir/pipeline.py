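"""End-to-end featurization: RNA records -> fused histogram tensors.

``SequenceFeaturizer`` is the trainable front half of the predictor. Fitting
trains, per RNA kind, the PV-DM sequence embedder and (when the graph
category is selected) the LNS similarity graph with its role-based node
embedder, on the provided records only — so cross-validation can fit it on
training-fold RNAs and still transform unseen test RNAs (doc2vec by
inference, graph by role lookup). Transforming yields one
20 x 20 x n_categories tensor per RNA.

Feature categories are nested ablation subsets: ("kmer",), ("kmer", "ctd"),
("kmer", "ctd", "doc2vec"), or all four. The graph category requires the
other three because the similarity graph is built over the union vectors.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .doc2vec import Doc2VecEncoder
from .features import (
    FeatureBundle,
    KS_LNC,
    KS_MIR,
    ctd_vector,
    kmer_vector,
    phase_subsequences,
)
from .fusion import FusedTensor, fuse_histogram
from .graph import LnsRoleEmbedder
from .io import RNARecord

__all__ = ["SequenceFeaturizer", "ALL_CATEGORIES", "FEATURE_SUBSETS"]

ALL_CATEGORIES = ("kmer", "ctd", "doc2vec", "graph")

#: The ablation ladder: each subset adds one category.
FEATURE_SUBSETS = {
    "kmer": ("kmer",),
    "kmer+ctd": ("kmer", "ctd"),
    "kmer+ctd+doc2vec": ("kmer", "ctd", "doc2vec"),
    "all": ALL_CATEGORIES,
}


class SequenceFeaturizer(TransformerMixin, BaseEstimator):
    """Per-kind trainable encoder stack producing fused histogram tensors.

    Parameters
    ----------
    categories : tuple of str
        Feature categories to encode (channel order of the output tensor).
    bins : int
        Histogram resolution per axis (tensors are bins x bins x n_cat).
    dim_lnc, dim_mir : int
        doc2vec dimensionality per kind (128 / 64).
    doc_epochs : int
        PV-DM training and inference epochs.
    graph_dim, k_nn, top_k, n_roles : int
        Node-embedding and LNS graph parameters.
    seed : int
        Controls every stochastic component; fitting is reproducible.
    """

    def __init__(
        self,
        categories: tuple[str, ...] = ALL_CATEGORIES,
        bins: int = 20,
        dim_lnc: int = 128,
        dim_mir: int = 64,
        doc_epochs: int = 40,
        doc_window: int = 5,
        graph_dim: int = 128,
        k_nn: int = 15,
        top_k: int = 15,
        n_roles: int = 32,
        n_walks: int = 10,
        walk_len: int = 40,
        seed: int = 0,
    ):
        self.categories = categories
        self.bins = bins
        self.dim_lnc = dim_lnc
        self.dim_mir = dim_mir
        self.doc_epochs = doc_epochs
        self.doc_window = doc_window
        self.graph_dim = graph_dim
        self.k_nn = k_nn
        self.top_k = top_k
        self.n_roles = n_roles
        self.n_walks = n_walks
        self.walk_len = walk_len
        self.seed = seed

    # -- helpers -----------------------------------------------------------

    def _needs_doc2vec(self) -> bool:
        return "doc2vec" in self.categories or "graph" in self.categories

    @staticmethod
    def _ks(kind: str) -> tuple[int, ...]:
        return KS_LNC if kind == "lncRNA" else KS_MIR

    def _union(self, rec: RNARecord, doc_vec: np.ndarray) -> np.ndarray:
        return np.concatenate(
            [kmer_vector(rec.seq, self._ks(rec.kind)), ctd_vector(rec.seq), doc_vec]
        )

    # -- estimator API -----------------------------------------------------

    def fit(self, X: Sequence[RNARecord], y=None):
        bad = set(self.categories) - set(ALL_CATEGORIES)
        if bad:
            raise ValueError(f"unknown feature categories: {sorted(bad)}")
        if "graph" in self.categories and not {"kmer", "ctd", "doc2vec"} <= set(
            self.categories
        ):
            raise ValueError("the graph category requires kmer, ctd and doc2vec")
        records = list(X)
        if not records:
            raise ValueError("no records to fit on")
        self.doc_models_: dict[str, Doc2VecEncoder] = {}
        self.graph_models_: dict[str, LnsRoleEmbedder] = {}
        for kind, dim in (("lncRNA", self.dim_lnc), ("miRNA", self.dim_mir)):
            kind_recs = [r for r in records if r.kind == kind]
            if not kind_recs:
                continue
            if self._needs_doc2vec():
                d2v = Doc2VecEncoder(
                    dim=dim,
                    window=self.doc_window,
                    epochs=self.doc_epochs,
                    seed=self.seed,
                ).fit(kind_recs)
                self.doc_models_[kind] = d2v
                if "graph" in self.categories and len(kind_recs) >= 2:
                    doc_vecs = d2v.transform(kind_recs)
                    U = np.array(
                        [self._union(r, v) for r, v in zip(kind_recs, doc_vecs)]
                    )
                    self.graph_models_[kind] = LnsRoleEmbedder(
                        dim=self.graph_dim,
                        k_nn=self.k_nn,
                        top_k=self.top_k,
                        n_roles=self.n_roles,
                        n_walks=self.n_walks,
                        walk_len=self.walk_len,
                        seed=self.seed,
                    ).fit(U)
        return self

    def bundle(self, rec: RNARecord) -> FeatureBundle:
        """Compute the per-phase feature bundle of one record."""
        if not hasattr(self, "doc_models_"):
            raise RuntimeError("SequenceFeaturizer is not fitted")
        phases = phase_subsequences(rec.seq)
        b = FeatureBundle(rna_id=rec.id, kind=rec.kind)
        ks = self._ks(rec.kind)
        for p, sub in enumerate(phases):
            if "kmer" in self.categories:
                b.vectors[(p, "kmer")] = kmer_vector(sub, ks)
            if "ctd" in self.categories:
                b.vectors[(p, "ctd")] = ctd_vector(sub)
        if self._needs_doc2vec():
            d2v = self.doc_models_[rec.kind]
            doc_vecs = d2v.transform(phases)
            if "doc2vec" in self.categories:
                for p in range(3):
                    b.vectors[(p, "doc2vec")] = doc_vecs[p]
            if "graph" in self.categories:
                emb = self.graph_models_[rec.kind]
                node_vec = emb.transform(self._union(rec, doc_vecs[0])[None, :])[0]
                # node embeddings have no phase structure; replicate phase 0
                for p in range(3):
                    b.vectors[(p, "graph")] = node_vec
        return b

    def transform(self, X: Iterable[RNARecord]) -> dict[str, FusedTensor]:
        """Map records to fused tensors, keyed by rna_id."""
        return {
            rec.id: fuse_histogram(self.bundle(rec), bins=self.bins, categories=self.categories)
            for rec in X
        }
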