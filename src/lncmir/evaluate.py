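"""Cross-validated evaluation of the full interaction-prediction pipeline.

``run_cv`` orchestrates the whole method: sample negatives once globally,
assign stratified folds at the pair level, and for each fold fit the
featurizer (doc2vec + similarity graph) on the RNAs of the training pairs
only, train the twin-tower CNN on the training-pair tensors, and score the
held-out pairs. Reports per-fold and mean +/- sd of SN/SP/ACC/F1/MCC and
AUC, plus ROC points.

Splitting at the pair level means an individual RNA may appear in both
training and test pairs (the sequences are shared resources; only the pair
labels are split). An optional strict mode assigns folds by lncRNA so test
lncRNAs are never seen in training pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cnn import TwinTowerClassifier
from .dataset import (
    confusion_from_calls,
    kfold_split,
    metrics,
    roc_auc,
    roc_points,
    sample_negatives,
)
from .io import InteractionPair, RNARecord
from .pipeline import ALL_CATEGORIES, SequenceFeaturizer

__all__ = ["CVConfig", "run_cv", "pair_arrays"]


@dataclass
class CVConfig:
    """Knobs of a cross-validation run."""

    beta: float = 1.0
    k: int = 5
    features: tuple[str, ...] = ALL_CATEGORIES
    entity_disjoint: bool = False
    seed: int = 0
    featurizer_params: dict = field(default_factory=dict)
    classifier_params: dict = field(default_factory=dict)


def pair_arrays(
    pairs: Sequence[InteractionPair], tensors: dict
) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair tensors into (X, y): X has shape (n, 2, bins, bins, n_cat)."""
    X = np.array(
        [[tensors[p.lnc_id].tensor, tensors[p.mir_id].tensor] for p in pairs]
    )
    y = np.array([p.label for p in pairs])
    return X, y


def _entity_folds(
    pairs: Sequence[InteractionPair], k: int, seed: int
) -> dict[tuple[str, str], int]:
    """Strict mode: fold by lncRNA, so held-out lncRNAs are unseen."""
    lnc_ids = sorted({p.lnc_id for p in pairs})
    rng = np.random.Generator(np.random.PCG64(seed))
    perm = rng.permutation(len(lnc_ids))
    fold_of_lnc = {lnc_ids[j]: int(i % k) for i, j in enumerate(perm)}
    return {p.key: fold_of_lnc[p.lnc_id] for p in pairs}


def run_cv(
    lncs: Sequence[RNARecord],
    mirs: Sequence[RNARecord],
    positives: Sequence[InteractionPair],
    config: CVConfig | None = None,
) -> dict:
    """Run k-fold cross-validation of the full pipeline; return the report.

    The report maps "folds" to a list of per-fold dicts (confusion counts,
    threshold metrics, AUC, ROC points), and "mean"/"sd" to aggregates over
    folds (undefined metrics are skipped in aggregation).
    """
    cfg = config or CVConfig()
    negatives = sample_negatives(lncs, mirs, positives, beta=cfg.beta, seed=cfg.seed)
    all_pairs = list(positives) + negatives
    assert not {p.key for p in negatives} & {p.key for p in positives}

    if cfg.entity_disjoint:
        folds = _entity_folds(all_pairs, cfg.k, cfg.seed)
    else:
        folds = kfold_split(all_pairs, k=cfg.k, seed=cfg.seed)

    rec_by_id = {r.id: r for r in list(lncs) + list(mirs)}
    fold_reports = []
    for f in range(cfg.k):
        train_pairs = [p for p in all_pairs if folds[p.key] != f]
        test_pairs = [p for p in all_pairs if folds[p.key] == f]
        if not train_pairs or not test_pairs:
            continue

        train_ids = {p.lnc_id for p in train_pairs} | {p.mir_id for p in train_pairs}
        train_records = [rec_by_id[i] for i in sorted(train_ids)]
        featurizer = SequenceFeaturizer(
            categories=cfg.features, seed=cfg.seed, **cfg.featurizer_params
        ).fit(train_records)

        needed = train_ids | {p.lnc_id for p in test_pairs} | {p.mir_id for p in test_pairs}
        tensors = featurizer.transform([rec_by_id[i] for i in sorted(needed)])

        X_tr, y_tr = pair_arrays(train_pairs, tensors)
        X_te, y_te = pair_arrays(test_pairs, tensors)

        clf = TwinTowerClassifier(seed=cfg.seed, **cfg.classifier_params).fit(X_tr, y_tr)
        probs = clf.predict_proba(X_te)[:, 1]
        calls = probs > 0.5

        conf = confusion_from_calls(y_te, calls)
        rep = {
            "fold": f,
            "n_train": len(train_pairs),
            "n_test": len(test_pairs),
            "confusion": {"TP": conf.TP, "FP": conf.FP, "TN": conf.TN, "FN": conf.FN},
            "metrics": metrics(conf),
            "auc": roc_auc(probs, y_te) if 0 < y_te.sum() < len(y_te) else None,
            "roc": roc_points(probs, y_te).tolist() if 0 < y_te.sum() < len(y_te) else [],
        }
        fold_reports.append(rep)

    metric_names = ["SN", "SP", "ACC", "F1", "MCC", "AUC"]
    mean, sd = {}, {}
    for name in metric_names:
        vals = [
            (r["auc"] if name == "AUC" else r["metrics"][name]) for r in fold_reports
        ]
        vals = [v for v in vals if v is not None]
        mean[name] = float(np.mean(vals)) if vals else None
        sd[name] = float(np.std(vals)) if vals else None

    return {
        "config": {
            "beta": cfg.beta,
            "k": cfg.k,
            "features": list(cfg.features),
            "entity_disjoint": cfg.entity_disjoint,
            "seed": cfg.seed,
        },
        "n_positive": len(positives),
        "n_negative": len(negatives),
        "folds": fold_reports,
        "mean": mean,
        "sd": sd,
    }
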