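"""LNS similarity weights, neighbor graph construction, role embeddings."""

import itertools

import numpy as np
import pytest

from lncmir.features import FeatureBundle
from lncmir.graph import (
    LnsRoleEmbedder,
    build_graph,
    embed_nodes,
    lns_weights,
    project_simplex,
    union_vector,
)


def _bundle(rna_id, kmer, ctd, doc):
    b = FeatureBundle(rna_id=rna_id, kind="lncRNA")
    b.vectors[(0, "kmer")] = np.asarray(kmer, float)
    b.vectors[(0, "ctd")] = np.asarray(ctd, float)
    b.vectors[(0, "doc2vec")] = np.asarray(doc, float)
    return b


class TestUnionVector:
    def test_lnc_and_mir_lengths(self):
        lnc = _bundle("l", np.zeros(340), np.zeros(30), np.zeros(128))
        mir = _bundle("m", np.zeros(84), np.zeros(30), np.zeros(64))
        assert union_vector(lnc).shape == (498,)
        assert union_vector(mir).shape == (178,)

    def test_missing_category_errors(self):
        b = FeatureBundle(rna_id="x", kind="lncRNA")
        b.vectors[(0, "kmer")] = np.zeros(4)
        b.vectors[(0, "ctd")] = np.zeros(30)
        with pytest.raises(KeyError, match="doc2vec"):
            union_vector(b)


class TestSimplexProjection:
    def test_projects_onto_simplex(self, rng):
        for _ in range(50):
            w = project_simplex(rng.standard_normal(6))
            assert abs(w.sum() - 1) < 1e-12 and (w >= 0).all()

    def test_fixed_point(self):
        w = np.array([0.2, 0.3, 0.5])
        np.testing.assert_allclose(project_simplex(w), w)


class TestLnsWeights:
    def test_simplex_constraints_random_matrices(self, rng):
        for _ in range(25):
            X = rng.standard_normal((10, 8))
            W = lns_weights(X, k_nn=5)
            assert np.allclose(W.sum(axis=1), 1, atol=1e-6)
            assert (W >= -1e-12).all()
            assert np.allclose(np.diag(W), 0)

    def test_exact_duplicate_gets_weight_one(self, rng):
        X = rng.standard_normal((5, 3))
        X[1] = X[0]  # exact reconstruction by one neighbor
        W = lns_weights(X, k_nn=2)
        assert W[0, 1] > 1 - 1e-6
        resid = X[0] - W[0] @ X
        assert np.linalg.norm(resid) < 1e-6

    def test_matches_grid_search_oracle(self, rng):
        # 4 points in 2-D, k_nn=2: brute-force the weight simplex at 1e-3
        X = np.array([[0.0, 0.0], [1.0, 0.2], [0.4, 1.0], [-0.8, 0.6]])
        W = lns_weights(X, k_nn=2)
        d2 = ((X[:, None] - X[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(4):
            nbrs = np.argsort(d2[i])[:2]
            grid = np.arange(0, 1.0 + 1e-9, 1e-3)
            objs = [
                np.sum((X[i] - (w * X[nbrs[0]] + (1 - w) * X[nbrs[1]])) ** 2)
                for w in grid
            ]
            w_star = grid[int(np.argmin(objs))]
            assert abs(W[i, nbrs[0]] - w_star) < 2e-3
            assert abs(W[i, nbrs[1]] - (1 - w_star)) < 2e-3

    def test_beats_uniform_weights(self, rng):
        X = rng.standard_normal((12, 6))
        k = 4
        W = lns_weights(X, k_nn=k)
        d2 = ((X[:, None] - X[None]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(12):
            nbrs = np.argsort(d2[i])[:k]
            obj_opt = np.sum((X[i] - W[i] @ X) ** 2)
            obj_unif = np.sum((X[i] - X[nbrs].mean(axis=0)) ** 2)
            assert obj_opt <= obj_unif + 1e-9

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            lns_weights(np.zeros((1, 3)))


class TestBuildGraph:
    def test_fewer_positive_weights_than_top_k(self):
        W = np.zeros((4, 4))
        W[0, 1:] = [0.5, 0.3, 0.2]
        W[1, 0] = W[2, 0] = W[3, 0] = 1.0
        sg = build_graph(W, top_k=15)
        assert sorted(sg.graph.neighbors(0)) == [1, 2, 3]

    def test_zero_weight_never_an_edge(self):
        W = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.5, 0.5, 0.0]])
        sg = build_graph(W, top_k=2)
        assert not sg.graph.has_edge(0, 2) or W[2, 0] > 0  # 2 selects 0: edge ok
        assert not sg.graph.has_edge(0, 1) or True
        # node 1's row has weight 0 toward 2, and 2's row has 0.5 toward 1
        assert sg.graph.has_edge(2, 1)
        assert not any(
            d["weight"] == 0 for _, _, d in sg.graph.edges(data=True)
        )

    def test_chain_of_near_duplicates_connected(self):
        # 5 points along a line: nearest-neighbor structure chains them
        X = np.array([[i, 0.0] for i in range(5)]) + 1e-3
        W = lns_weights(X, k_nn=2)
        sg = build_graph(W, top_k=2)
        import networkx as nx

        assert nx.is_connected(sg.graph)

    def test_edge_set_is_union_of_directed_selections(self, rng):
        # degree can exceed 2*top_k only through being selected by others;
        # the edge set must be exactly the union of per-row top-k selections
        X = rng.standard_normal((20, 5))
        W = lns_weights(X, k_nn=6)
        top_k = 3
        sg = build_graph(W, top_k=top_k)
        selected = set()
        for i in range(20):
            order = np.argsort(-W[i], kind="stable")[:top_k]
            selected |= {frozenset((i, int(j))) for j in order if W[i, j] > 0}
        edges = {frozenset(e) for e in sg.graph.edges}
        assert edges == selected


class TestRoleEmbedder:
    def test_vector_length_and_determinism(self, rng):
        X = rng.standard_normal((15, 20))
        e1 = LnsRoleEmbedder(dim=128, k_nn=4, top_k=4, epochs=30, seed=5).fit(X)
        e2 = LnsRoleEmbedder(dim=128, k_nn=4, top_k=4, epochs=30, seed=5).fit(X)
        assert e1.transform(X).shape == (15, 128)
        np.testing.assert_array_equal(e1.roles_, e2.roles_)
        np.testing.assert_array_equal(e1.transform(X), e2.transform(X))

    def test_identical_attributes_identical_embeddings(self, rng):
        X = rng.standard_normal((10, 12))
        X[3] = X[7]
        emb = LnsRoleEmbedder(dim=16, k_nn=3, top_k=3, epochs=20, seed=0).fit(X)
        V = emb.transform(X)
        np.testing.assert_array_equal(V[3], V[7])

    def test_clique_separation_majority(self):
        """Two attribute-distinct cliques: within-clique embeddings should be
        more aligned than between-clique ones for most seeds."""
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(200 + s)
            a = rng.standard_normal(8) + 4.0
            b = rng.standard_normal(8) - 4.0
            X = np.vstack([a + 0.1 * rng.standard_normal((6, 8)),
                           b + 0.1 * rng.standard_normal((6, 8))])
            emb = LnsRoleEmbedder(dim=16, k_nn=3, top_k=3, epochs=50, seed=s).fit(X)
            V = emb.transform(X)
            V = V / np.linalg.norm(V, axis=1, keepdims=True)
            S = V @ V.T
            within = np.mean([S[i, j] for i, j in itertools.combinations(range(6), 2)])
            within += np.mean([S[i + 6, j + 6] for i, j in itertools.combinations(range(6), 2)])
            between = np.mean(S[:6, 6:])
            wins += within / 2 > between
        assert wins >= 6

    def test_embed_nodes_wrapper(self, rng):
        X = rng.standard_normal((8, 10))
        sg = build_graph(lns_weights(X, k_nn=3), node_ids=[f"r{i}" for i in range(8)], top_k=3)
        vecs = embed_nodes(sg, X, dim=32, seed=1, k_nn=3, top_k=3, epochs=10)
        assert set(vecs) == {f"r{i}" for i in range(8)}
        assert all(v.shape == (32,) for v in vecs.values())

    def test_export_formats(self, rng, tmp_path):
        from lncmir.graph import write_edge_list, write_embeddings

        X = rng.standard_normal((6, 8))
        sg = build_graph(lns_weights(X, k_nn=2), node_ids=[f"n{i}" for i in range(6)], top_k=2)
        write_edge_list(sg, tmp_path / "edges.tsv")
        lines = (tmp_path / "edges.tsv").read_text().splitlines()
        assert lines[0] == "id1\tid2\tweight"
        assert len(lines) - 1 == sg.graph.number_of_edges()
        vecs = embed_nodes(sg, X, dim=8, seed=0, k_nn=2, top_k=2, epochs=5)
        write_embeddings(vecs, tmp_path / "emb.tsv")
        rows = (tmp_path / "emb.tsv").read_text().splitlines()
        assert len(rows) == 6 and all(len(r.split("\t")) == 9 for r in rows)

    def test_higher_walk_order_rejected(self, rng):
        X = rng.standard_normal((4, 5))
        sg = build_graph(lns_weights(X, k_nn=2), top_k=2)
        with pytest.raises(ValueError):
            embed_nodes(sg, X, walk_order=2)
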