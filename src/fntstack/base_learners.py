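"""The nine confidence-emitting base classifiers and out-of-fold stacking.

The fixed roster, in the column order ``c1..c9`` used everywhere downstream:

    c1 gcforest  multi-grained cascade forest (:mod:`fntstack.deep_forest`)
    c2 svm       support vector machine (RBF, Platt-calibrated)
    c3 rf        random forest
    c4 adaboost  AdaBoost over decision stumps
    c5 dtree     CART decision tree
    c6 gbdt      gradient-boosted decision trees
    c7 knn       k-nearest neighbours
    c8 logreg    logistic regression
    c9 nbayes    Gaussian naive Bayes

All eight scikit-learn members run with library-default hyperparameters; a
"confidence" is always the positive-class probability.  The stacking matrix
is produced out-of-fold by default so the meta-learner never sees a
prediction made by a model trained on that row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .deep_forest import CascadeConfig, GcForestConfig, GcForestClassifier, ScanConfig
from .evaluation import StratificationError, stratified_fold_assignment

LEARNER_NAMES = (
    "gcforest",
    "svm",
    "rf",
    "adaboost",
    "dtree",
    "gbdt",
    "knn",
    "logreg",
    "nbayes",
)


class LearnerError(ValueError):
    pass


@dataclass
class LearnerSpec:
    """One named base classifier; empty hyperparameters mean library defaults."""

    name: str
    hyperparameters: Dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in LEARNER_NAMES:
            raise LearnerError(
                f"unknown learner {self.name!r}; expected one of "
                f"{LEARNER_NAMES}"
            )


@dataclass
class ConfidenceMatrix:
    """n x 9 positive-class confidences, columns in the fixed learner order."""

    values: np.ndarray
    column_names: tuple
    row_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(
            self.column_names
        ):
            raise LearnerError(
                f"confidence matrix shape {self.values.shape} does not match "
                f"{len(self.column_names)} columns"
            )
        if ((self.values < 0) | (self.values > 1)).any():
            raise LearnerError("confidences must lie in [0, 1]")


def default_specs(
    seed: int = 0, gcforest_config: Optional[GcForestConfig] = None
) -> List[LearnerSpec]:
    """The nine learners in canonical order, sharing a base seed."""
    specs = []
    for name in LEARNER_NAMES:
        hp = {}
        if name == "gcforest" and gcforest_config is not None:
            hp["config"] = gcforest_config
        specs.append(LearnerSpec(name=name, hyperparameters=hp, seed=seed))
    return specs


def make_estimator(spec: LearnerSpec):
    """Instantiate the scikit-learn (or deep-forest) estimator for a spec."""
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.name == "gcforest":
        config = hp.pop("config", None)
        return GcForestClassifier(config=config, random_state=seed)
    if spec.name == "svm":
        # SVC emits margins only; probability=True turns on Platt scaling so
        # the output is a calibrated positive-class probability.
        return SVC(probability=True, random_state=seed, **hp)
    if spec.name == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if spec.name == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if spec.name == "dtree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.name == "gbdt":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if spec.name == "knn":
        return KNeighborsClassifier(**hp)
    if spec.name == "logreg":
        hp.setdefault("max_iter", 1000)
        return LogisticRegression(**hp)
    if spec.name == "nbayes":
        return GaussianNB(**hp)
    raise LearnerError(f"unknown learner {spec.name!r}")


def fit_learner(spec: LearnerSpec, X, y):
    """Fit one base learner; requires both classes present."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise LearnerError("labels contain a single class")
    est = make_estimator(spec)
    est.fit(np.asarray(X, dtype=float), y)
    # fallback confidence when a learner's likelihoods degenerate (e.g.
    # naive Bayes on zero-variance features): the training class prior
    est._positive_prior = float(np.mean(y == 1))
    return est


def learner_confidence(fitted, X) -> np.ndarray:
    """Positive-class probability per row, clipped to [0, 1]."""
    proba = fitted.predict_proba(np.asarray(X, dtype=float))
    classes = np.asarray(fitted.classes_)
    col = int(np.where(classes == 1)[0][0])
    conf = proba[:, col]
    bad = ~np.isfinite(conf)
    if bad.any():
        conf = np.where(bad, getattr(fitted, "_positive_prior", 0.5), conf)
    return np.clip(conf, 0.0, 1.0)


def out_of_fold_confidences(
    specs: Sequence[LearnerSpec],
    X,
    y,
    k_inner: int = 5,
    seed: int = 0,
    row_ids: Optional[Sequence] = None,
) -> ConfidenceMatrix:
    """Leakage-safe stacking confidences: row i is scored only by models
    whose training folds excluded row i.

    Folds are stratified and keyed to the row id (see
    :func:`fntstack.evaluation.stratified_fold_assignment`), so permuting the
    table rows permutes the matrix identically.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if row_ids is None:
        row_ids = np.arange(len(y))
    row_ids = np.asarray(row_ids)
    if k_inner < 2:
        raise StratificationError("k_inner must be >= 2")
    folds = stratified_fold_assignment(row_ids, y, k_inner, seed)

    values = np.empty((len(y), len(specs)))
    for f in range(k_inner):
        test = folds == f
        for j, spec in enumerate(specs):
            fitted = fit_learner(spec, X[~test], y[~test])
            values[test, j] = learner_confidence(fitted, X[test])
    return ConfidenceMatrix(
        values=values,
        column_names=tuple(s.name for s in specs),
        row_ids=row_ids,
    )


def resubstitution_confidences(
    specs: Sequence[LearnerSpec],
    X,
    y,
    row_ids: Optional[Sequence] = None,
) -> ConfidenceMatrix:
    """In-sample stacking confidences (each learner scores its own training
    rows) — optimistic, provided for comparison with the out-of-fold default."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if row_ids is None:
        row_ids = np.arange(len(y))
    values = np.empty((len(y), len(specs)))
    for j, spec in enumerate(specs):
        fitted = fit_learner(spec, X, y)
        values[:, j] = learner_confidence(fitted, X)
    return ConfidenceMatrix(
        values=values,
        column_names=tuple(s.name for s in specs),
        row_ids=np.asarray(row_ids),
    )
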