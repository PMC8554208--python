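"""Deep forest (gcForest): multi-grained scanning + cascade forest.

Multi-grained scanning slides windows of ``k`` contiguous features over each
``m``-dimensional sample, producing ``s = (m - k) + 1`` sub-vectors per
window.  Every sub-vector is scored by a completely-random forest (each
split on a uniformly random feature, trees grown to purity) and an ordinary
random forest; the two-class probability vectors of all sub-vectors and
windows are spliced into one representation of width ``4 s`` per window.

The cascade stacks layers of one completely-random forest and one random
forest.  Layer ``t`` receives the scanned representation concatenated with
layer ``t - 1``'s class vectors; the final layer's class vectors are
averaged and the argmax taken as the label (ties resolved to the positive
class).  Layer growth stops when internal cross-validated accuracy stops
improving, or at ``max_layers``.

Scanning and cascade probabilities used during fitting are produced
out-of-fold so downstream layers never see resubstitution scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold


class DeepForestError(ValueError):
    pass


@dataclass
class ScanConfig:
    """Multi-grained scanning settings.

    ``window_sizes`` empty means auto: ``ceil(m/4)`` and ``ceil(m/2)``.
    """

    window_sizes: Tuple[int, ...] = ()
    trees_per_forest: int = 30
    cv_folds: int = 3
    seed: int = 0


@dataclass
class CascadeConfig:
    trees_per_forest: int = 100
    forests_per_layer: int = 2  # one completely-random + one random forest
    max_layers: int = 10
    patience: int = 1
    cv_folds: int = 3
    seed: int = 0


@dataclass
class GcForestConfig:
    scan: ScanConfig = field(default_factory=ScanConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)


def _completely_random_forest(n_trees: int, seed: int) -> ExtraTreesClassifier:
    # One random candidate feature per split with a random threshold, grown
    # to leaf purity.
    return ExtraTreesClassifier(
        n_estimators=n_trees, max_features=1, random_state=seed, n_jobs=1
    )


def _random_forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )


def _proba_01(forest, X: np.ndarray) -> np.ndarray:
    """Class-probability pairs ordered (class 0, class 1)."""
    proba = forest.predict_proba(X)
    order = np.argsort(forest.classes_)
    return proba[:, order]


def resolve_windows(m: int, window_sizes: Sequence[int]) -> Tuple[int, ...]:
    if window_sizes:
        windows = tuple(int(k) for k in window_sizes)
    else:
        windows = (max(1, -(-m // 4)), max(2, -(-m // 2)))
    for k in windows:
        if not 1 <= k < m:
            raise DeepForestError(
                f"window size {k} must satisfy 1 <= k < m={m}"
            )
    return windows


def _subvectors(X: np.ndarray, k: int) -> np.ndarray:
    """Stack the ``s = m - k + 1`` contiguous windows: shape (n*s, k)."""
    windows = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)
    n, s, _ = windows.shape
    return np.ascontiguousarray(windows).reshape(n * s, k), s


class MultiGrainedScanner:
    """Fits the per-window forests and emits spliced representations."""

    def __init__(self, config: Optional[ScanConfig] = None):
        self.config = config or ScanConfig()
        self.windows_: Tuple[int, ...] = ()
        self.forests_: List[Tuple[object, object]] = []
        self.n_features_: Optional[int] = None

    def fit_transform(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Fit and return the out-of-fold training representation.

        Sub-vectors of a sample always share its fold, so no forest scores
        a sub-vector of a sample it was trained on.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n, m = X.shape
        self.n_features_ = m
        self.windows_ = resolve_windows(m, self.config.window_sizes)
        cfg = self.config
        skf = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True, random_state=cfg.seed
        )
        folds = list(skf.split(X, y))
        blocks = []
        self.forests_ = []
        for wi, k in enumerate(self.windows_):
            sub, s = _subvectors(X, k)
            sub_y = np.repeat(y, s)
            pair = []
            for fi, make in enumerate(
                (_completely_random_forest, _random_forest)
            ):
                seed = cfg.seed + 101 * wi + 11 * fi
                oof = np.empty((n * s, 2))
                for train_idx, test_idx in folds:
                    train_rows = (
                        (train_idx[:, None] * s) + np.arange(s)
                    ).ravel()
                    test_rows = ((test_idx[:, None] * s) + np.arange(s)).ravel()
                    forest = make(cfg.trees_per_forest, seed)
                    forest.fit(sub[train_rows], sub_y[train_rows])
                    oof[test_rows] = _proba_01(forest, sub[test_rows])
                blocks.append(oof.reshape(n, s * 2))
                final = make(cfg.trees_per_forest, seed)
                final.fit(sub, sub_y)
                pair.append(final)
            self.forests_.append(tuple(pair))
        return np.hstack(blocks)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.n_features_ is None:
            raise DeepForestError("scanner is not fitted")
        if X.shape[1] != self.n_features_:
            raise DeepForestError(
                f"expected {self.n_features_} features, got {X.shape[1]}"
            )
        blocks = []
        for k, pair in zip(self.windows_, self.forests_):
            sub, s = _subvectors(X, k)
            for forest in pair:
                blocks.append(_proba_01(forest, sub).reshape(len(X), s * 2))
        return np.hstack(blocks)


def multi_grained_scan(
    X: np.ndarray, y: np.ndarray, config: Optional[ScanConfig] = None
) -> np.ndarray:
    """Out-of-fold scanned representation of the training table."""
    return MultiGrainedScanner(config).fit_transform(X, y)


@dataclass
class _Layer:
    forests: Tuple[object, ...]
    cv_accuracy: float


@dataclass
class CascadeModel:
    layers: List[_Layer]
    n_layers_used: int
    stop_reason: str
    input_width: int
    class_count: int = 2


def _labels_from_vectors(vectors: np.ndarray) -> np.ndarray:
    # Argmax with ties resolved to the positive class.
    return (vectors[:, 1] >= vectors[:, 0]).astype(int)


def cascade_fit(
    R: np.ndarray, y: np.ndarray, config: Optional[CascadeConfig] = None
) -> CascadeModel:
    """Grow the cascade layer by layer with early stopping.

    Each layer's class vectors are generated out-of-fold (``cv_folds``) both
    to feed the next layer and to measure the accuracy driving the stopping
    rule; the stored forests are refit on all rows for prediction.
    """
    config = config or CascadeConfig()
    R = np.asarray(R, dtype=float)
    y = np.asarray(y)
    if R.size == 0:
        raise DeepForestError("empty representation")
    if len(np.unique(y)) < 2:
        raise DeepForestError("labels contain a single class")

    n = len(y)
    makers = (_completely_random_forest, _random_forest)[: config.forests_per_layer]
    while len(makers) < config.forests_per_layer:
        makers = makers + (_random_forest,)

    layers: List[_Layer] = []
    aug: Optional[np.ndarray] = None
    best_acc = -np.inf
    best_depth = 0
    stale = 0
    stop_reason = "max_layers"
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed
    )
    folds = list(skf.split(R, y))

    for t in range(config.max_layers):
        layer_input = R if aug is None else np.hstack([R, aug])
        oof_vectors = []
        fitted = []
        for fi, make in enumerate(makers):
            seed = config.seed + 1009 * t + 13 * fi
            oof = np.empty((n, 2))
            for train_idx, test_idx in folds:
                forest = make(config.trees_per_forest, seed)
                forest.fit(layer_input[train_idx], y[train_idx])
                oof[test_idx] = _proba_01(forest, layer_input[test_idx])
            oof_vectors.append(oof)
            final = make(config.trees_per_forest, seed)
            final.fit(layer_input, y)
            fitted.append(final)
        mean_vec = np.mean(oof_vectors, axis=0)
        acc = float(np.mean(_labels_from_vectors(mean_vec) == y))
        layers.append(_Layer(tuple(fitted), acc))
        if acc > best_acc + 1e-12:
            best_acc = acc
            best_depth = t + 1
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                stop_reason = "no_improvement"
                break
        aug = np.hstack(oof_vectors)

    return CascadeModel(
        layers=layers[:best_depth] if best_depth else layers[:1],
        n_layers_used=max(best_depth, 1),
        stop_reason=stop_reason,
        input_width=R.shape[1],
    )


def cascade_predict(model: CascadeModel, R: np.ndarray) -> np.ndarray:
    """Propagate ``R`` through the cascade; return (n, 2) class vectors.

    The final layer's forest vectors are averaged; rows sum to 1.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[1] != model.input_width:
        raise DeepForestError(
            f"representation width {R.shape[1]} != training width "
            f"{model.input_width}"
        )
    aug = None
    vectors = None
    for layer in model.layers[: model.n_layers_used]:
        layer_input = R if aug is None else np.hstack([R, aug])
        per_forest = [_proba_01(f, layer_input) for f in layer.forests]
        aug = np.hstack(per_forest)
        vectors = np.mean(per_forest, axis=0)
    return vectors


class GcForestClassifier:
    """sklearn-style wrapper: scan, cascade, average, argmax."""

    def __init__(
        self,
        config: Optional[GcForestConfig] = None,
        random_state: Optional[int] = None,
    ):
        self.config = config or GcForestConfig()
        if random_state is not None:
            self.config = GcForestConfig(
                scan=ScanConfig(
                    window_sizes=self.config.scan.window_sizes,
                    trees_per_forest=self.config.scan.trees_per_forest,
                    cv_folds=self.config.scan.cv_folds,
                    seed=random_state,
                ),
                cascade=CascadeConfig(
                    trees_per_forest=self.config.cascade.trees_per_forest,
                    forests_per_layer=self.config.cascade.forests_per_layer,
                    max_layers=self.config.cascade.max_layers,
                    patience=self.config.cascade.patience,
                    cv_folds=self.config.cascade.cv_folds,
                    seed=random_state,
                ),
            )
        self.scanner_: Optional[MultiGrainedScanner] = None
        self.cascade_: Optional[CascadeModel] = None
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        self.scanner_ = MultiGrainedScanner(self.config.scan)
        R = self.scanner_.fit_transform(X, y)
        self.cascade_ = cascade_fit(R, np.asarray(y), self.config.cascade)
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.scanner_ is None or self.cascade_ is None:
            raise DeepForestError("classifier is not fitted")
        R = self.scanner_.transform(np.asarray(X, dtype=float))
        return cascade_predict(self.cascade_, R)

    def predict(self, X) -> np.ndarray:
        return _labels_from_vectors(self.predict_proba(X))


def gcforest_fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    X_new: np.ndarray,
    config: Optional[GcForestConfig] = None,
) -> np.ndarray:
    """Fit on ``(X, y)`` and return positive-class confidences for ``X_new``."""
    clf = GcForestClassifier(config)
    clf.fit(X, y)
    return clf.predict_proba(X_new)[:, 1]
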