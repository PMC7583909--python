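"""Histogram fusion: shape, mass conservation, oracle agreement, invariances."""

import numpy as np
import pytest

from lncmir.features import FeatureBundle
from lncmir.fusion import PHASE_PAIRS, FusedTensor, fuse_histogram, pair_tensor


def _bundle(values_by_cat: dict[str, np.ndarray]) -> FeatureBundle:
    """values_by_cat[cat] has shape (3, d): one vector per phase."""
    b = FeatureBundle(rna_id="x", kind="lncRNA")
    for cat, arr in values_by_cat.items():
        for p in range(3):
            b.vectors[(p, cat)] = np.asarray(arr[p], float)
    return b


def _brute_force_channel(phases: np.ndarray, bins: int) -> np.ndarray:
    """Independent oracle: normalize, enumerate every point, bin by hand."""
    lo, hi = phases.min(), phases.max()
    norm = (phases - lo) / (hi - lo) if hi > lo else np.zeros_like(phases)
    h = np.zeros((bins, bins))
    for a, b in PHASE_PAIRS:
        for i in range(phases.shape[1]):
            x, y = norm[a, i], norm[b, i]
            xi = min(int(x * bins), bins - 1)
            yi = min(int(y * bins), bins - 1)
            h[xi, yi] += 1
    return h


class TestFuseHistogram:
    def test_channel_order_and_shape(self, rng):
        arrs = {c: rng.random((3, 7)) for c in ("kmer", "ctd", "doc2vec", "graph")}
        ft = fuse_histogram(_bundle(arrs))
        assert ft.tensor.shape == (20, 20, 4)
        assert ft.categories == ("kmer", "ctd", "doc2vec", "graph")

    def test_mass_conservation_per_channel(self, rng):
        dims = {"kmer": 340, "ctd": 30, "doc2vec": 128, "graph": 128}
        arrs = {c: rng.random((3, d)) for c, d in dims.items()}
        ft = fuse_histogram(_bundle(arrs))
        for ci, cat in enumerate(ft.categories):
            assert ft.tensor[:, :, ci].sum() == 3 * dims[cat]

    def test_agrees_with_brute_force_oracle(self, rng):
        arrs = {c: rng.random((3, 4)) for c in ("kmer", "ctd", "doc2vec", "graph")}
        ft = fuse_histogram(_bundle(arrs), bins=20)
        for ci, cat in enumerate(ft.categories):
            np.testing.assert_array_equal(
                ft.tensor[:, :, ci], _brute_force_channel(arrs[cat], 20)
            )

    def test_degenerate_constant_category_in_corner(self):
        arrs = {"kmer": np.full((3, 6), 2.5)}
        ft = fuse_histogram(_bundle(arrs), categories=("kmer",))
        chan = ft.tensor[:, :, 0]
        assert chan[0, 0] == 3 * 6
        assert chan.sum() == 3 * 6

    def test_right_edge_inclusive(self):
        # a maximal value (normalized to exactly 1.0) lands in the last bin
        arr = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        ft = fuse_histogram(_bundle({"kmer": arr}), categories=("kmer",), bins=4)
        assert ft.tensor[3, 3, 0] == 3  # the all-ones dimension, all 3 phase pairs

    def test_permutation_invariance(self, rng):
        arr = rng.random((3, 9))
        perm = rng.permutation(9)
        a = fuse_histogram(_bundle({"ctd": arr}), categories=("ctd",)).tensor
        b = fuse_histogram(_bundle({"ctd": arr[:, perm]}), categories=("ctd",)).tensor
        np.testing.assert_array_equal(a, b)

    def test_positive_scaling_invariance(self, rng):
        arr = rng.random((3, 9))
        a = fuse_histogram(_bundle({"ctd": arr}), categories=("ctd",)).tensor
        b = fuse_histogram(_bundle({"ctd": 7.3 * arr}), categories=("ctd",)).tensor
        np.testing.assert_array_equal(a, b)

    def test_missing_phase_errors(self):
        b = FeatureBundle(rna_id="x", kind="lncRNA")
        b.vectors[(0, "kmer")] = np.zeros(4)
        with pytest.raises(KeyError):
            fuse_histogram(b, categories=("kmer",))

    def test_bins_validation(self, rng):
        arrs = {"kmer": rng.random((3, 4))}
        with pytest.raises(ValueError):
            fuse_histogram(_bundle(arrs), bins=1, categories=("kmer",))


class TestPairTensor:
    def test_valid_pair_passes_through(self, rng):
        t = rng.random((20, 20, 4))
        a = FusedTensor("l", t, ("kmer", "ctd", "doc2vec", "graph"))
        b = FusedTensor("m", np.zeros((20, 20, 4)), ("kmer", "ctd", "doc2vec", "graph"))
        ta, tb = pair_tensor(a, b)
        assert ta.shape == tb.shape == (20, 20, 4)
        np.testing.assert_array_equal(ta, t)

    def test_shape_mismatch_errors(self):
        a = FusedTensor("l", np.zeros((19, 20, 4)), tuple("abcd"))
        b = FusedTensor("m", np.zeros((20, 20, 4)), tuple("abcd"))
        with pytest.raises(ValueError, match="mismatch"):
            pair_tensor(a, b)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            FusedTensor("x", -np.ones((20, 20, 4)), tuple("abcd"))
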