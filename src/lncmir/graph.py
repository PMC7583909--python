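"""Linear-neighborhood similarity graphs and role-based node embeddings.

Each RNA kind (lncRNA, miRNA) gets its own homogeneous similarity graph:
every RNA is reconstructed as a convex combination of its k nearest
neighbors in union-feature space (k-mer | CTD | doc2vec concatenation), the
simplex-constrained reconstruction weights serve as similarity, and each
node keeps edges to its top-15 positive-weight neighbors.

Nodes are then embedded with an attribute-aware random-walk scheme in the
role2vec family: each node is mapped to a discrete role by median-binning a
random projection of its attributes, memoryless (order-1) random walks are
re-written as role sequences, and a skip-gram model over roles yields the
128-dimensional node vectors. Because roles are a function of attributes
alone, unseen RNAs can be embedded after fitting by role lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._sgns import SkipGramSoftmax
from .features import FeatureBundle

__all__ = [
    "SimilarityGraph",
    "union_vector",
    "lns_weights",
    "build_graph",
    "embed_nodes",
    "LnsRoleEmbedder",
    "project_simplex",
]

logger = logging.getLogger(__name__)


def union_vector(bundle: FeatureBundle) -> np.ndarray:
    """Concatenate the whole-sequence (phase-0) kmer | ctd | doc2vec vectors.

    Length 498 for lncRNAs (340+30+128), 178 for miRNAs (84+30+64).
    """
    return np.concatenate(
        [bundle.get(0, "kmer"), bundle.get(0, "ctd"), bundle.get(0, "doc2vec")]
    )


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (Duchi et al.)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u)
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > (css - 1))[0][-1]
    theta = (css[rho] - 1.0) / (rho + 1)
    return np.maximum(v - theta, 0.0)


def _solve_simplex_lsq(
    Xn: np.ndarray, x: np.ndarray, max_iter: int = 1000, tol: float = 1e-8
) -> np.ndarray:
    """min ||x - Xn^T w||^2 over the simplex, by projected gradient descent."""
    k = Xn.shape[0]
    G = Xn @ Xn.T
    b = Xn @ x
    # Lipschitz constant of the gradient = largest eigenvalue of G
    lip = float(np.linalg.eigvalsh(G)[-1])
    step = 1.0 / lip if lip > 0 else 1.0
    w = np.full(k, 1.0 / k)
    for _ in range(max_iter):
        w_new = project_simplex(w - step * (G @ w - b))
        if np.max(np.abs(w_new - w)) < tol:
            w = w_new
            break
        w = w_new
    return w


def lns_weights(X: np.ndarray, k_nn: int = 15) -> np.ndarray:
    """Linear-neighborhood similarity matrix by simplex-constrained least squares.

    Row i holds the weights reconstructing sample i from its ``k_nn``
    Euclidean-nearest other samples: non-negative, summing to 1, zero outside
    the neighborhood and on the diagonal.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("LNS needs at least 2 samples")
    k_nn = min(k_nn, n - 1)
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        nbrs = np.argsort(d2[i], kind="stable")[:k_nn]
        W[i, nbrs] = _solve_simplex_lsq(X[nbrs], X[i])
    return W


@dataclass
class SimilarityGraph:
    """LNS weight matrix plus the derived top-k neighbor graph."""

    node_ids: list[str]
    W: np.ndarray
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)


def build_graph(
    W: np.ndarray, node_ids: list[str] | None = None, top_k: int = 15
) -> SimilarityGraph:
    """Link every node to its up-to-``top_k`` highest-weight positive neighbors.

    The graph is undirected: an edge exists if either endpoint selects the
    other. Weight-0 entries never produce edges.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if node_ids is None:
        node_ids = [str(i) for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        order = np.argsort(-W[i], kind="stable")[:top_k]
        for j in order:
            if W[i, j] > 0:
                w = max(W[i, j], W[j, i])
                g.add_edge(i, int(j), weight=float(w))
    return SimilarityGraph(node_ids=list(node_ids), W=W, graph=g)


def _random_walks(
    g: nx.Graph, n_walks: int, walk_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Memoryless uniform random walks, ``n_walks`` per node; shape (n*n_walks, walk_len)."""
    n = g.number_of_nodes()
    nbr_lists = [np.array(sorted(g.neighbors(i)), dtype=np.int64) for i in range(n)]
    deg = np.array([len(nb) for nb in nbr_lists])
    offsets = np.concatenate([[0], np.cumsum(deg)])
    flat = np.concatenate([nb for nb in nbr_lists]) if deg.sum() else np.zeros(0, np.int64)

    starts = np.repeat(np.arange(n), n_walks)
    walks = np.empty((len(starts), walk_len), dtype=np.int64)
    walks[:, 0] = starts
    cur = starts.copy()
    for t in range(1, walk_len):
        movable = deg[cur] > 0
        pick = offsets[cur] + (rng.random(len(cur)) * np.maximum(deg[cur], 1)).astype(np.int64)
        nxt = cur.copy()
        if movable.any():
            nxt[movable] = flat[pick[movable]]
        walks[:, t] = nxt
        cur = nxt
    return walks


class LnsRoleEmbedder(TransformerMixin, BaseEstimator):
    """LNS graph + role-based random-walk node embedding, as a transformer.

    ``fit`` takes the (n_samples, n_features) matrix of union vectors, builds
    the LNS similarity graph, assigns each node a discrete role (2-bin median
    split per dimension of a random projection, hashed into ``n_roles``
    buckets), runs order-1 random walks re-written as role sequences, and
    trains skip-gram role vectors. ``transform`` maps (possibly unseen)
    union vectors to the vector of their role.

    Attributes
    ----------
    similarity_graph_ : SimilarityGraph
        The fitted LNS graph over the training samples.
    roles_ : ndarray of shape (n_samples,)
        Role index of each training sample.
    role_vectors_ : ndarray of shape (n_roles, dim)
        Skip-gram embedding of each role.
    """

    def __init__(
        self,
        dim: int = 128,
        k_nn: int = 15,
        top_k: int = 15,
        n_roles: int = 32,
        proj_dim: int = 64,
        n_walks: int = 10,
        walk_len: int = 40,
        window: int = 5,
        epochs: int = 200,
        seed: int = 0,
    ):
        self.dim = dim
        self.k_nn = k_nn
        self.top_k = top_k
        self.n_roles = n_roles
        self.proj_dim = proj_dim
        self.n_walks = n_walks
        self.walk_len = walk_len
        self.window = window
        self.epochs = epochs
        self.seed = seed

    # -- role assignment ---------------------------------------------------

    def _assign_roles(self, X: np.ndarray) -> np.ndarray:
        Z = X @ self.projection_
        bits = (Z > self.medians_).astype(np.uint64)
        return ((bits * self.hash_vec_).sum(axis=1) % np.uint64(self.n_roles)).astype(int)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 samples")
        rng = np.random.Generator(np.random.PCG64(self.seed))

        p = min(self.proj_dim, X.shape[1])
        self.projection_ = rng.standard_normal((X.shape[1], p))
        Z = X @ self.projection_
        self.medians_ = np.median(Z, axis=0)
        self.hash_vec_ = rng.integers(1, 2**31, size=p).astype(np.uint64) * np.uint64(2) + np.uint64(1)
        self.roles_ = self._assign_roles(X)

        W = lns_weights(X, self.k_nn)
        self.similarity_graph_ = build_graph(W, top_k=self.top_k)

        walks = _random_walks(self.similarity_graph_.graph, self.n_walks, self.walk_len, rng)
        role_walks = [self.roles_[w] for w in walks]
        sg = SkipGramSoftmax(
            dim=self.dim,
            window=self.window,
            epochs=self.epochs,
            seed=self.seed,
        ).fit(role_walks, vocab_size=self.n_roles)
        self.role_vectors_ = sg.W_in_

        present = np.unique(np.concatenate(role_walks))
        missing = np.setdiff1d(self.roles_, present)
        if missing.size:
            logger.warning("roles %s never appear in any walk; zero vectors", missing)
            self.role_vectors_[missing] = 0.0
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "role_vectors_"):
            raise RuntimeError("LnsRoleEmbedder is not fitted")
        X = np.asarray(X, dtype=float)
        return self.role_vectors_[self._assign_roles(X)]


def write_edge_list(sg: SimilarityGraph, path) -> None:
    """Export the neighbor graph as TSV: id1, id2, weight."""
    with open(path, "w") as fh:
        fh.write("id1\tid2\tweight\n")
        for i, j, d in sg.graph.edges(data=True):
            fh.write(f"{sg.node_ids[i]}\t{sg.node_ids[j]}\t{d['weight']:.6g}\n")


def write_embeddings(vectors: dict[str, np.ndarray], path) -> None:
    """Export node embeddings as TSV: id followed by the vector components."""
    with open(path, "w") as fh:
        for rid, vec in vectors.items():
            fh.write(rid + "\t" + "\t".join(f"{v:.6g}" for v in vec) + "\n")


def embed_nodes(
    graph: SimilarityGraph,
    attributes: np.ndarray,
    dim: int = 128,
    walk_order: int = 1,
    seed: int = 0,
    **params,
) -> dict[str, np.ndarray]:
    """Embed the nodes of a prebuilt similarity graph; returns id -> vector.

    Only order-1 (memoryless) walks are supported; the walk is a Markov chain
    on the current node.
    """
    if walk_order != 1:
        raise ValueError("only walk_order=1 (memoryless walks) is supported")
    emb = LnsRoleEmbedder(dim=dim, seed=seed, **params)
    # reuse the given graph instead of refitting LNS
    X = np.asarray(attributes, dtype=float)
    rng = np.random.Generator(np.random.PCG64(seed))
    p = min(emb.proj_dim, X.shape[1])
    emb.projection_ = rng.standard_normal((X.shape[1], p))
    Z = X @ emb.projection_
    emb.medians_ = np.median(Z, axis=0)
    emb.hash_vec_ = rng.integers(1, 2**31, size=p).astype(np.uint64) * np.uint64(2) + np.uint64(1)
    emb.roles_ = emb._assign_roles(X)
    emb.similarity_graph_ = graph
    walks = _random_walks(graph.graph, emb.n_walks, emb.walk_len, rng)
    role_walks = [emb.roles_[w] for w in walks]
    sg = SkipGramSoftmax(dim=dim, window=emb.window, epochs=emb.epochs, seed=seed).fit(
        role_walks, vocab_size=emb.n_roles
    )
    emb.role_vectors_ = sg.W_in_
    vecs = emb.role_vectors_[emb.roles_]
    return {rid: vecs[i] for i, rid in enumerate(graph.node_ids)}
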