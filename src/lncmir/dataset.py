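"""Negative-pair sampling, cross-validation folds, and evaluation metrics.

Negatives are drawn by the shuffle-and-reject scheme: both identifier lists
are shuffled ten times with the Knuth-Durstenfeld (Fisher-Yates) algorithm,
then pairs are drawn uniformly (one id from each list) and kept iff they are
neither known positives nor already-sampled negatives, until beta x
n_positives negatives are collected. Folds are stratified by label.

Metrics follow the usual confusion-table closed forms — sensitivity,
specificity, accuracy, F1 and the Matthews correlation coefficient (with
the square root in the denominator) — plus the Mann-Whitney (midrank)
formulation of ROC AUC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .io import InteractionPair, RNARecord

__all__ = [
    "ConfusionCounts",
    "sample_negatives",
    "knuth_durstenfeld_shuffle",
    "kfold_split",
    "metrics",
    "confusion_from_calls",
    "roc_auc",
    "roc_points",
]

_REJECTION_CAP = 10_000_000


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN counts of a binary evaluation."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def knuth_durstenfeld_shuffle(items: list, rng: np.random.Generator) -> list:
    """In-place Fisher-Yates shuffle (Knuth-Durstenfeld variant); returns items."""
    for i in range(len(items) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        items[i], items[j] = items[j], items[i]
    return items


def sample_negatives(
    lncs: Sequence[RNARecord | str],
    mirs: Sequence[RNARecord | str],
    positives: Sequence[InteractionPair],
    beta: float = 1.0,
    seed: int = 0,
) -> list[InteractionPair]:
    """Sample round(beta x n_positives) non-interacting pairs.

    Both id lists are shuffled 10 times with the Knuth-Durstenfeld algorithm,
    then (lnc, mir) pairs are drawn uniformly with rejection of known
    positives and duplicates. Deterministic for a fixed seed.
    """
    lnc_ids = [r.id if isinstance(r, RNARecord) else str(r) for r in lncs]
    mir_ids = [r.id if isinstance(r, RNARecord) else str(r) for r in mirs]
    pos_keys = {p.key for p in positives}
    n_target = int(round(beta * len(positives)))
    universe = len(lnc_ids) * len(mir_ids)
    if n_target > universe - len(pos_keys):
        raise ValueError(
            f"cannot sample {n_target} negatives: only {universe - len(pos_keys)} "
            f"non-positive pairs exist"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    for _ in range(10):
        knuth_durstenfeld_shuffle(lnc_ids, rng)
        knuth_durstenfeld_shuffle(mir_ids, rng)

    negatives: list[InteractionPair] = []
    seen: set[tuple[str, str]] = set()
    draws = 0
    while len(negatives) < n_target:
        if draws >= _REJECTION_CAP:
            raise RuntimeError(f"rejection sampling exceeded {_REJECTION_CAP} draws")
        li = int(rng.integers(0, len(lnc_ids)))
        mi = int(rng.integers(0, len(mir_ids)))
        draws += 1
        key = (lnc_ids[li], mir_ids[mi])
        if key in pos_keys or key in seen:
            continue
        seen.add(key)
        negatives.append(InteractionPair(key[0], key[1], label=0, source="sampled"))
    return negatives


def kfold_split(
    pairs: Sequence[InteractionPair],
    k: int = 5,
    seed: int = 0,
    stratify: bool = True,
) -> dict[tuple[str, str], int]:
    """Assign each pair a fold index in {0..k-1}.

    Stratified by label (fold positive fractions within one pair of the
    global fraction); fold sizes differ by at most 1. Returns a mapping
    (lnc_id, mir_id) -> fold.
    """
    if len(pairs) < k:
        raise ValueError(f"need at least k={k} pairs, got {len(pairs)}")
    labels = np.array([p.label for p in pairs])
    if stratify and len(np.unique(labels)) > 1:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(len(pairs)), labels)
    else:
        from sklearn.model_selection import KFold

        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(len(pairs)))
    assignment: dict[tuple[str, str], int] = {}
    for fold, (_, test_idx) in enumerate(split_iter):
        for i in test_idx:
            assignment[pairs[i].key] = fold
    return assignment


def confusion_from_calls(y_true: np.ndarray, calls: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    calls = np.asarray(calls).astype(bool)
    return ConfusionCounts(
        TP=int(np.sum(y_true & calls)),
        FP=int(np.sum(~y_true & calls)),
        TN=int(np.sum(~y_true & ~calls)),
        FN=int(np.sum(y_true & ~calls)),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """SN, SP, ACC, F1 and MCC from a confusion table.

    A metric whose denominator is zero is reported as None (undefined),
    never silently as 0.
    """
    tp, fp, tn, fn = c.TP, c.FP, c.TN, c.FN

    def _ratio(num: float, den: float) -> float | None:
        return num / den if den > 0 else None

    mcc_den = np.sqrt(float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    return {
        "SN": _ratio(tp, tp + fn),
        "SP": _ratio(tn, tn + fp),
        "ACC": _ratio(tp + tn, c.total),
        "F1": _ratio(2 * tp, 2 * tp + fp + fn),
        "MCC": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else None,
    }


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """ROC AUC by the Mann-Whitney rank statistic with midranks for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: Sequence[float], labels: Sequence[int]) -> np.ndarray:
    """ROC curve points as an array of (FPR, TPR) rows, threshold descending."""
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])
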