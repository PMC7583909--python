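"""Negative sampling, fold assignment, confusion metrics, ROC AUC."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from lncmir.dataset import (
    ConfusionCounts,
    confusion_from_calls,
    kfold_split,
    knuth_durstenfeld_shuffle,
    metrics,
    roc_auc,
    roc_points,
    sample_negatives,
)
from lncmir.io import InteractionPair, RNARecord


def _pairs(n_pos, n_neg=0):
    pos = [InteractionPair(f"l{i}", f"m{i % 7}", 1) for i in range(n_pos)]
    neg = [InteractionPair(f"l{i}", f"m{(i + 3) % 7}", 0, "sampled") for i in range(n_pos, n_pos + n_neg)]
    return pos + neg


class TestSampleNegatives:
    def test_balanced_count_and_disjointness(self, fixture_corpus):
        lncs, mirs, pos = fixture_corpus
        negs = sample_negatives(lncs, mirs, pos, beta=1.0, seed=3)
        assert len(negs) == len(pos) == 100
        assert not {p.key for p in negs} & {p.key for p in pos}
        assert len({p.key for p in negs}) == len(negs)
        assert all(p.label == 0 and p.source == "sampled" for p in negs)

    def test_beta_ratio(self, fixture_corpus):
        lncs, mirs, pos = fixture_corpus
        assert len(sample_negatives(lncs, mirs, pos, beta=0.25, seed=0)) == 25
        assert len(sample_negatives(lncs, mirs, pos, beta=2.0, seed=0)) == 200

    def test_exhausted_universe_errors(self):
        lncs = [RNARecord(f"l{i}", "ACGT" * 60, "lncRNA") for i in range(2)]
        mirs = [RNARecord(f"m{i}", "ACGTACGTACGTACGTACGTA", "miRNA") for i in range(2)]
        pos = [InteractionPair(l.id, m.id, 1) for l in lncs for m in mirs]
        with pytest.raises(ValueError, match="cannot sample"):
            sample_negatives(lncs, mirs, pos, beta=1.0, seed=0)

    def test_deterministic_per_seed(self, fixture_corpus):
        lncs, mirs, pos = fixture_corpus
        a = sample_negatives(lncs, mirs, pos, seed=11)
        b = sample_negatives(lncs, mirs, pos, seed=11)
        assert [p.key for p in a] == [p.key for p in b]

    def test_shuffle_is_permutation(self, rng):
        items = list(range(50))
        out = knuth_durstenfeld_shuffle(list(items), rng)
        assert sorted(out) == items and out != items


class TestKfold:
    def test_partition_and_sizes(self):
        pairs = _pairs(60, 40)
        folds = kfold_split(pairs, k=5, seed=0)
        assert set(folds) == {p.key for p in pairs}
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_remainder_rule(self):
        pairs = _pairs(101)
        # single-class set: falls back to unstratified equal split
        sizes = np.bincount(list(kfold_split(pairs, k=5, seed=0).values()))
        assert sorted(sizes) == [20, 20, 20, 20, 21]

    def test_stratification_within_one_pair(self):
        pairs = _pairs(60, 40)
        folds = kfold_split(pairs, k=5, seed=1)
        by_label = {p.key: p.label for p in pairs}
        for f in range(5):
            keys = [k for k, v in folds.items() if v == f]
            n_pos = sum(by_label[k] for k in keys)
            assert abs(n_pos - 12) <= 1  # global fraction 60/100 over folds of 20
        assert kfold_split(pairs, k=5, seed=1) == folds  # deterministic

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            kfold_split(_pairs(3), k=5)


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(TP=10, FP=0, TN=10, FN=0))
        assert all(m[k] == 1 for k in ("SN", "SP", "ACC", "F1", "MCC"))

    def test_symmetric_counts(self):
        m = metrics(ConfusionCounts(TP=1, FP=1, TN=1, FN=1))
        assert m["F1"] == 0.5 and m["MCC"] == 0

    def test_closed_forms(self):
        m = metrics(ConfusionCounts(TP=50, FP=10, TN=40, FN=5))
        assert m["SN"] == 50 / 55
        assert m["SP"] == 40 / 50
        assert m["ACC"] == 90 / 105
        assert m["F1"] == 100 / 115
        mcc = (50 * 40 - 10 * 5) / np.sqrt(55 * 60 * 50 * 45)
        assert abs(m["MCC"] - mcc) < 1e-12

    def test_zero_denominator_reported_undefined(self):
        m = metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=0))
        assert m["SN"] is None and m["MCC"] is None
        assert m["SP"] == 1.0

    def test_mcc_equals_pearson_on_random_tables(self, rng):
        """The closed form must match the Pearson correlation of the binary
        prediction/truth vectors reconstructed from the table."""
        for _ in range(100):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            m = metrics(ConfusionCounts(TP=int(tp), FP=int(fp), TN=int(tn), FN=int(fn)))
            y_true = np.r_[np.ones(tp), np.zeros(fp), np.zeros(tn), np.ones(fn)]
            y_pred = np.r_[np.ones(tp), np.ones(fp), np.zeros(tn), np.zeros(fn)]
            r = pearsonr(y_true, y_pred).statistic
            assert abs(m["MCC"] - r) < 1e-10

    def test_confusion_from_calls(self):
        c = confusion_from_calls([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.TP, c.FN, c.TN, c.FP) == (2, 1, 1, 1)
        assert c.total == 5


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_scores_tied_gives_half(self):
        assert roc_auc([0.5] * 10, [1] * 5 + [0] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_permutation_null_near_half(self, rng):
        labels = rng.integers(0, 2, 1000)
        scores = rng.random(1000)
        assert 0.45 <= roc_auc(scores, labels) <= 0.55

    def test_matches_sklearn_with_ties(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 200)
        scores = rng.integers(0, 5, 200) / 4  # heavy ties
        assert abs(roc_auc(scores, labels) - roc_auc_score(labels, scores)) < 1e-12

    def test_roc_points_monotone(self, rng):
        pts = roc_points(rng.random(50), rng.integers(0, 2, 50))
        assert (np.diff(pts[:, 0]) >= 0).all()
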