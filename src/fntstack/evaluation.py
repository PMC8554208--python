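"""Binary-classification evaluation: confusion metrics, ROC/AUC, k-fold CV.

The cross-validation harness is stratified (the active/decoy tables are
1:3 imbalanced, which makes unstratified 15-fold splits fragile) and pools
the out-of-fold predictions: the reported confusion is the sum over folds
and the ROC is computed on the concatenated held-out scores, giving a
single metric set per fold count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, roc_curve

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RocCurve",
    "CrossValResult",
    "EvaluationError",
    "StratificationError",
    "confusion",
    "metrics",
    "roc_auc",
    "stratified_fold_assignment",
    "cross_validate",
]


class EvaluationError(ValueError):
    pass


class StratificationError(EvaluationError):
    pass


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


@dataclass
class MetricSet:
    tpr: float
    fpr: float
    precision: float
    specificity: float
    f1: float


@dataclass
class RocCurve:
    """Ordered ROC points from a full threshold sweep, with trapezoidal AUC.

    The point list starts at (0, 0), ends at (1, 1) and is nondecreasing in
    both coordinates; the trapezoidal area equals the Mann-Whitney rank
    statistic (ties counted 1/2).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Exact confusion counts for 0/1 label vectors of equal length."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise EvaluationError(
            f"length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    tn, fp, fn, tp = confusion_matrix(
        y_true, y_pred, labels=[0, 1]
    ).ravel()
    return ConfusionCounts(tp=int(tp), fp=int(fp), fn=int(fn), tn=int(tn))


def metrics(counts: ConfusionCounts) -> MetricSet:
    """TPR, FPR, precision, specificity and F1 from confusion counts.

    Conventions for empty denominators: precision is 1 when there are no
    positive predictions; F1 is 0 when precision and TPR are both 0.  Both
    truth classes must be present.
    """
    if counts.positives == 0 or counts.negatives == 0:
        raise EvaluationError("both truth classes must be present")
    tpr = counts.tp / counts.positives
    fpr = counts.fp / counts.negatives
    precision = (
        counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 1.0
    )
    specificity = counts.tn / counts.negatives
    f1 = (
        2 * precision * tpr / (precision + tpr)
        if precision + tpr > 0
        else 0.0
    )
    return MetricSet(
        tpr=tpr, fpr=fpr, precision=precision, specificity=specificity, f1=f1
    )


def roc_auc(y_true, scores) -> RocCurve:
    """ROC from a sweep over every unique score, with trapezoidal AUC."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise EvaluationError("both classes required for a ROC curve")
    fpr, tpr, thresholds = roc_curve(y_true, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def stratified_fold_assignment(
    row_ids: Sequence, y, k: int, seed: int
) -> np.ndarray:
    """Fold index per row, stratified by class and keyed to the row id.

    Within each class, rows are taken in canonical (sorted-id) order,
    shuffled by a seed-only generator, and dealt to folds cyclically, so the
    id -> fold map does not depend on the order rows arrive in and per-class
    fold sizes differ by at most one.
    """
    y = np.asarray(y)
    row_ids = np.asarray(row_ids)
    if k < 2:
        raise StratificationError("k must be >= 2")
    folds = np.empty(len(y), dtype=int)
    rng = np.random.default_rng(seed)
    for cls in sorted(np.unique(y)):
        idx = np.where(y == cls)[0]
        if len(idx) < k:
            raise StratificationError(
                f"class {cls} has {len(idx)} rows, fewer than k={k}; a fold "
                "would lose the class"
            )
        canonical = idx[np.argsort(row_ids[idx], kind="stable")]
        perm = rng.permutation(len(canonical))
        folds[canonical[perm]] = np.arange(len(canonical)) % k
    return folds


@dataclass
class CrossValResult:
    fold_metrics: List[MetricSet]
    fold_confusions: List[ConfusionCounts]
    pooled_confusion: ConfusionCounts
    pooled_metrics: MetricSet
    pooled_roc: RocCurve
    fold_assignment: np.ndarray


def cross_validate(
    X,
    y,
    model_builder: Callable,
    k: int,
    seed: int = 0,
    row_ids: Optional[Sequence] = None,
    threshold: float = 0.5,
) -> CrossValResult:
    """Stratified k-fold evaluation of a confidence-scoring model.

    ``model_builder(X_train, y_train)`` must return a callable mapping a
    feature matrix to positive-class confidences.  Hard labels use
    ``confidence >= threshold``.  Per-fold confusions are summed into the
    pooled confusion; the pooled ROC uses the concatenated held-out scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if row_ids is None:
        row_ids = np.arange(len(y))
    folds = stratified_fold_assignment(row_ids, y, k, seed)

    fold_metrics: List[MetricSet] = []
    fold_confusions: List[ConfusionCounts] = []
    oof_scores = np.empty(len(y), dtype=float)
    for f in range(k):
        test = folds == f
        scorer = model_builder(X[~test], y[~test])
        scores = np.asarray(scorer(X[test]), dtype=float)
        oof_scores[test] = scores
        counts = confusion(y[test], (scores >= threshold).astype(int))
        fold_confusions.append(counts)
        fold_metrics.append(metrics(counts))

    pooled = fold_confusions[0]
    for c in fold_confusions[1:]:
        pooled = pooled + c
    return CrossValResult(
        fold_metrics=fold_metrics,
        fold_confusions=fold_confusions,
        pooled_confusion=pooled,
        pooled_metrics=metrics(pooled),
        pooled_roc=roc_auc(y, oof_scores),
        fold_assignment=folds,
    )
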