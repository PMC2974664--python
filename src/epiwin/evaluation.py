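"""Threshold-dependent performance measures, threshold scanning and 5-fold
cross-validation.

Measures follow the standard residue-classification conventions:
Sen = 100·TP/(TP+FN), Spe = 100·TN/(TN+FP), Acc = 100·(TP+TN)/total, and the
Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))

with MCC defined as 0 (and flagged) when any denominator factor vanishes.
A positive call is score >= Thr (inclusive).  The operating point reported
for a model is the scanned threshold minimizing |Sen − Spe|, so sensitivity
and specificity balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .encoders import Encoding, PropertyScaleTable, encode_patterns
from .model import SVMConfig, predict_scores, train
from .patterns import PatternSet

#: Default threshold grid: covers every operating threshold the method uses.
DEFAULT_THRESHOLDS = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.1), 10)


class ConfusionCounts(NamedTuple):
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsRow:
    threshold: float
    sen: float
    spe: float
    acc: float
    mcc: float
    mcc_degenerate: bool = False


def confusion(
    scores: np.ndarray, labels: np.ndarray, thr: float
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN at a threshold; positive call iff score >= thr."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores ({scores.shape}) and labels ({labels.shape}) differ in length"
        )
    calls = scores >= thr
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(calls & pos)),
        FP=int(np.sum(calls & ~pos)),
        TN=int(np.sum(~calls & ~pos)),
        FN=int(np.sum(~calls & pos)),
    )


def metrics(counts: ConfusionCounts, threshold: float = math.nan) -> MetricsRow:
    """Sen/Spe/Acc as percentages and MCC from a confusion tally."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    sen = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spe = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / counts.total
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    degenerate = denom == 0
    mcc = 0.0 if degenerate else (tp * tn - fp * fn) / math.sqrt(denom)
    return MetricsRow(threshold, sen, spe, acc, mcc, degenerate)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve swept over all distinct score thresholds."""
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC AUC requires both classes in the labels")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """ROC curve points (FPR, TPR, threshold) for reporting/plotting."""
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


@dataclass
class ScanResult:
    rows: pd.DataFrame
    selected: MetricsRow  # the row minimizing |Sen - Spe|


def threshold_scan(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> ScanResult:
    """One metrics row per threshold plus the balanced operating point.

    The selected row minimizes |Sen − Spe| (ties broken toward the lowest
    threshold), the rule used to pick each model's reported Thr*.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("threshold grid is empty")
    rows = [metrics(confusion(scores, labels, t), threshold=t) for t in thresholds]
    gaps = [abs(r.sen - r.spe) for r in rows]
    selected = rows[int(np.argmin(gaps))]
    frame = pd.DataFrame(
        {
            "threshold": [r.threshold for r in rows],
            "sen": [r.sen for r in rows],
            "spe": [r.spe for r in rows],
            "acc": [r.acc for r in rows],
            "mcc": [r.mcc for r in rows],
        }
    )
    return ScanResult(frame, selected)


@dataclass
class CVResult:
    """Cross-validation outcome at the selected operating threshold.

    ``per_fold`` holds one metrics row per fold evaluated at the single
    operating threshold selected on the pooled out-of-fold scores;
    ``mean_row`` averages them (the headline numbers); ``pooled_row``
    recomputes the metrics from summed counts for transparency, and
    ``pooled_auc``/``mean_auc`` are the threshold-independent summaries.
    """

    per_fold: pd.DataFrame
    mean_row: MetricsRow
    pooled_row: MetricsRow
    pooled_auc: float
    mean_auc: float
    selected_threshold: float
    fold_sizes: list[int]


def _fold_assignment(
    pattern_set: PatternSet,
    k: int,
    split_unit: Literal["pattern", "antigen"],
    seed: int,
) -> np.ndarray:
    n = len(pattern_set.patterns)
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if split_unit == "pattern":
        perm = rng.permutation(n)
        # remainder spread one-per-fold so sizes differ by <= 1
        for fold, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = fold
    elif split_unit == "antigen":
        ids = sorted({p.antigen_id for p in pattern_set.patterns})
        order = rng.permutation(len(ids))
        fold_of_id = {ids[j]: i % k for i, j in enumerate(order)}
        for i, p in enumerate(pattern_set.patterns):
            folds[i] = fold_of_id[p.antigen_id]
    else:
        raise ValueError(f"unknown split unit {split_unit!r}")
    return folds


def cross_validate(
    pattern_set: PatternSet,
    encoding: Encoding,
    W: int,
    config: SVMConfig,
    k: int = 5,
    split_unit: Literal["pattern", "antigen"] = "pattern",
    seed: int = 0,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    scales: PropertyScaleTable | None = None,
) -> CVResult:
    """k-fold cross-validation with a threshold scan on pooled scores.

    The data are randomly divided into k near-equal sets; each is used once
    for testing with the rest for training.  Out-of-fold decision scores are
    pooled, the operating threshold Thr* minimizing |Sen − Spe| is selected
    on the pool, per-fold metrics are computed at that Thr* and averaged.
    ``split_unit='antigen'`` keeps all patterns of one antigen in one fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    patterns = pattern_set.patterns
    if encoding == "ppp" and scales is None:
        scales = PropertyScaleTable.default()
    X, y = encode_patterns(patterns, encoding, scales=scales)
    folds = _fold_assignment(pattern_set, k, split_unit, seed)

    oof_scores = np.empty(len(patterns))
    fold_sizes = []
    for fold in range(k):
        test = folds == fold
        y_train = y[~test]
        if len(np.unique(y_train)) < 2 or len(np.unique(y[test])) < 2:
            raise ValueError(
                f"fold {fold} has a single class; try antigen-level split or "
                "a different seed"
            )
        model = train(X[~test], y_train, config, seed=seed, encoding=encoding, W=W)
        oof_scores[test] = predict_scores(model, X[test])
        fold_sizes.append(int(test.sum()))

    scan = threshold_scan(oof_scores, y, thresholds)
    thr_star = scan.selected.threshold

    fold_rows = []
    fold_aucs = []
    pooled = np.zeros(4, dtype=int)
    for fold in range(k):
        test = folds == fold
        counts = confusion(oof_scores[test], y[test], thr_star)
        pooled += np.array(counts)
        fold_rows.append(metrics(counts, threshold=thr_star))
        fold_aucs.append(roc_auc(oof_scores[test], y[test]))

    per_fold = pd.DataFrame(
        {
            "fold": range(k),
            "n": fold_sizes,
            "sen": [r.sen for r in fold_rows],
            "spe": [r.spe for r in fold_rows],
            "acc": [r.acc for r in fold_rows],
            "mcc": [r.mcc for r in fold_rows],
            "auc": fold_aucs,
        }
    )
    mean_row = MetricsRow(
        threshold=thr_star,
        sen=float(np.mean([r.sen for r in fold_rows])),
        spe=float(np.mean([r.spe for r in fold_rows])),
        acc=float(np.mean([r.acc for r in fold_rows])),
        mcc=float(np.mean([r.mcc for r in fold_rows])),
    )
    pooled_row = metrics(ConfusionCounts(*pooled.tolist()), threshold=thr_star)
    return CVResult(
        per_fold=per_fold,
        mean_row=mean_row,
        pooled_row=pooled_row,
        pooled_auc=roc_auc(oof_scores, y),
        mean_auc=float(np.mean(fold_aucs)),
        selected_threshold=float(thr_star),
        fold_sizes=fold_sizes,
    )
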