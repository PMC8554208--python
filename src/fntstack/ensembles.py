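"""Stacked ensembles: the FNT meta-learner and the two classical baselines.

The core object is :class:`FNTStackingModel`: nine heterogeneous base
classifiers produce positive-class confidences ``c = (c1..c9)`` which feed
an evolved flexible neural tree acting as a nonlinear combiner.  ``fit()``
returns an :class:`FNTStackingResults` carrying the fitted tree, the
deployed base learners, the evolution diagnostics, ``summary()``, prediction
and persistence.  The averaged (soft mean) and majority-vote ensembles are
provided as module functions for comparison.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .base_learners import (
    ConfidenceMatrix,
    LearnerSpec,
    default_specs,
    fit_learner,
    learner_confidence,
    out_of_fold_confidences,
    resubstitution_confidences,
)
from .deep_forest import GcForestConfig
from .evolve import EvolutionConfig, EvolutionResult, evolve
from .tree import (
    FlexibleNeuralTree,
    deserialize_tree,
    evaluate_tree_batch,
    serialize_tree,
    tree_complexity,
)


class EnsembleError(ValueError):
    pass


@dataclass
class StackingConfig:
    """How the meta-learner's training confidences are produced.

    ``protocol="oof"`` (default) uses stratified ``k_inner``-fold
    out-of-fold predictions, so the tree never trains on leaked in-sample
    confidences; ``"resub"`` uses each learner's resubstitution output.
    """

    k_inner: int = 5
    protocol: str = "oof"
    seed: int = 0
    threshold: float = 0.5

    def validate(self) -> None:
        if self.protocol not in ("oof", "resub"):
            raise EnsembleError("protocol must be 'oof' or 'resub'")
        if not 0.0 < self.threshold < 1.0:
            raise EnsembleError("threshold must lie in (0, 1)")


class FNTStackingModel:
    """Nine base classifiers + an evolved FNT combiner, built from data.

    Parameters
    ----------
    X, y
        Numeric feature matrix and binary activity labels.
    row_ids
        Optional stable row identifiers (fold assignment is keyed to them).
    evolution_config, stacking_config
        Budgets and protocols; library defaults otherwise.
    gcforest_config
        Passed to the deep-forest base learner.
    """

    def __init__(
        self,
        X,
        y,
        row_ids: Optional[Sequence] = None,
        learner_specs: Optional[List[LearnerSpec]] = None,
        evolution_config: Optional[EvolutionConfig] = None,
        stacking_config: Optional[StackingConfig] = None,
        gcforest_config: Optional[GcForestConfig] = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise EnsembleError("X must be 2-D with one label per row")
        if len(np.unique(self.y)) < 2:
            raise EnsembleError("labels contain a single class")
        self.row_ids = (
            np.arange(len(self.y)) if row_ids is None else np.asarray(row_ids)
        )
        self.stacking_config = stacking_config or StackingConfig()
        self.stacking_config.validate()
        self.evolution_config = evolution_config or EvolutionConfig(
            seed=self.stacking_config.seed
        )
        self.learner_specs = learner_specs or default_specs(
            seed=self.stacking_config.seed, gcforest_config=gcforest_config
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_column: str = "label",
        id_column: Optional[str] = None,
        **kwargs,
    ) -> "FNTStackingModel":
        """Build from a table whose columns are id (optional), descriptors
        and a binary label column."""
        if label_column not in df.columns:
            raise EnsembleError(f"label column {label_column!r} not found")
        df = df.copy()
        if id_column is not None:
            row_ids = df.pop(id_column).to_numpy()
        else:
            row_ids = df.index.to_numpy()
        y = df.pop(label_column).to_numpy()
        return cls(df.to_numpy(dtype=float), y, row_ids=row_ids, **kwargs)

    def fit(self) -> "FNTStackingResults":
        """Stack: out-of-fold confidences -> evolve the FNT -> refit the
        nine learners on all rows for deployment."""
        sc = self.stacking_config
        if sc.protocol == "oof":
            C = out_of_fold_confidences(
                self.learner_specs,
                self.X,
                self.y,
                k_inner=sc.k_inner,
                seed=sc.seed,
                row_ids=self.row_ids,
            )
        else:
            C = resubstitution_confidences(
                self.learner_specs, self.X, self.y, row_ids=self.row_ids
            )
        evolution = evolve(C.values, self.y, self.evolution_config)
        deployed = {
            spec.name: fit_learner(spec, self.X, self.y)
            for spec in self.learner_specs
        }
        return FNTStackingResults(
            model=self,
            tree=evolution.best_tree,
            evolution=evolution,
            confidence_matrix=C,
            learners=deployed,
            threshold=sc.threshold,
        )


@dataclass
class FNTStackingResults:
    """Fitted stacker: evolved tree, deployed base learners, diagnostics."""

    model: FNTStackingModel
    tree: FlexibleNeuralTree
    evolution: EvolutionResult
    confidence_matrix: ConfidenceMatrix
    learners: Dict[str, object]
    threshold: float = 0.5

    def base_confidences(self, X_new) -> np.ndarray:
        """n x 9 matrix of deployed-learner confidences for new rows."""
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim != 2 or X_new.shape[1] != self.model.X.shape[1]:
            raise EnsembleError(
                f"expected {self.model.X.shape[1]} features, got shape "
                f"{X_new.shape}"
            )
        cols = [
            learner_confidence(self.learners[spec.name], X_new)
            for spec in self.model.learner_specs
        ]
        return np.column_stack(cols)

    def predict_confidence(self, X_new) -> np.ndarray:
        """FNT output on the nine deployed-learner confidences; in (0, 1]."""
        return evaluate_tree_batch(self.tree, self.base_confidences(X_new))

    def predict(self, X_new):
        """(confidence, label) per row; label = confidence >= threshold."""
        conf = self.predict_confidence(X_new)
        return conf, (conf >= self.threshold).astype(int)

    def training_fit(self) -> float:
        """Fitness of the tree on the stacking matrix (lower is better)."""
        return self.evolution.best_fitness

    def summary(self) -> str:
        """Plain-text fit report."""
        nodes, depth = tree_complexity(self.tree)
        sc = self.model.stacking_config
        ec = self.model.evolution_config
        C = self.confidence_matrix
        out = evaluate_tree_batch(self.tree, C.values)
        acc = float(np.mean((out >= self.threshold) == (self.model.y == 1)))
        lines = [
            "FNT stacking ensemble",
            "=" * 53,
            f"training rows:          {len(self.model.y)} "
            f"({int(self.model.y.sum())} active / "
            f"{int((1 - self.model.y).sum())} decoy)",
            f"stacking protocol:      {sc.protocol} "
            f"(k_inner={sc.k_inner}, seed={sc.seed})",
            f"evolution budget:       population {ec.population_size}, "
            f"{ec.generations} generations, seed {ec.seed}",
            f"fitness evaluations:    {self.evolution.evaluations}",
            f"best fitness (RMSE+pc): {self.evolution.best_fitness:.6f}",
            f"tree size:              {nodes} nodes, depth {depth}",
            f"training accuracy:      {acc:.4f} "
            f"(threshold {self.threshold})",
            "meta-learner tree:",
            f"  {serialize_tree(self.tree)}",
            "base learner columns:   "
            + ", ".join(
                f"c{j + 1}={name}" for j, name in enumerate(C.column_names)
            ),
        ]
        return "\n".join(lines)

    def plot_evolution(self, ax=None):
        """Best/mean fitness per generation."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hist = np.asarray(self.evolution.history)
        ax.plot(hist[:, 0], label="best")
        ax.plot(hist[:, 1], label="population mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("fitness (RMSE + parsimony)")
        ax.legend()
        return ax

    def save(self, directory) -> None:
        """Persist to a directory: tree s-expression, pickled learners and a
        JSON manifest (seeds, config echo, column order)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "tree.sexp").write_text(
            serialize_tree(self.tree) + "\n"
        )
        with open(directory / "learners.pkl", "wb") as fh:
            pickle.dump(self.learners, fh)
        manifest = {
            "columns": [
                f"c{j + 1}:{name}"
                for j, name in enumerate(self.confidence_matrix.column_names)
            ],
            "threshold": self.threshold,
            "n_features": int(self.model.X.shape[1]),
            "stacking": asdict(self.model.stacking_config),
            "evolution": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.model.evolution_config).items()
            },
            "best_fitness": self.evolution.best_fitness,
        }
        (directory / "manifest.json").write_text(
            json.dumps(manifest, indent=2) + "\n"
        )


def load_results(directory) -> "FNTStackingResults":
    """Reload a saved stacker for prediction.

    Returns a results object with prediction support; the training-time
    diagnostics (history, confidence matrix) are not persisted.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    column_names = tuple(c.split(":", 1)[1] for c in manifest["columns"])
    tree = deserialize_tree(
        (directory / "tree.sexp").read_text().strip(),
        n_inputs=len(column_names),
    )
    with open(directory / "learners.pkl", "rb") as fh:
        learners = pickle.load(fh)
    n_features = manifest["n_features"]
    dummy_X = np.zeros((2, n_features))
    dummy_y = np.array([0, 1])
    model = FNTStackingModel.__new__(FNTStackingModel)
    model.X = dummy_X
    model.y = dummy_y
    model.row_ids = np.arange(2)
    model.stacking_config = StackingConfig(**manifest["stacking"])
    model.evolution_config = EvolutionConfig(
        **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in manifest["evolution"].items()
        }
    )
    model.learner_specs = [LearnerSpec(name=n) for n in column_names]
    return FNTStackingResults(
        model=model,
        tree=tree,
        evolution=EvolutionResult(tree, manifest["best_fitness"], [], 0),
        confidence_matrix=ConfidenceMatrix(
            values=np.zeros((1, len(column_names))),
            column_names=column_names,
            row_ids=np.array([0]),
        ),
        learners=learners,
        threshold=manifest["threshold"],
    )


# ---------------------------------------------------------------------------
# Spec-surface convenience functions and the two baseline ensembles
# ---------------------------------------------------------------------------

def fit_fnt_stacker(
    X,
    y,
    evolution_config: Optional[EvolutionConfig] = None,
    stacking_config: Optional[StackingConfig] = None,
    **kwargs,
) -> FNTStackingResults:
    """One-call stacker fit; see :class:`FNTStackingModel`."""
    return FNTStackingModel(
        X,
        y,
        evolution_config=evolution_config,
        stacking_config=stacking_config,
        **kwargs,
    ).fit()


def predict_fnt_stacker(results: FNTStackingResults, X_new):
    """(confidence, label) per row of ``X_new``."""
    return results.predict(X_new)


def averaged_ensemble(C: ConfidenceMatrix) -> np.ndarray:
    """Soft ensemble: arithmetic mean of the nine confidences per row."""
    return C.values.mean(axis=1)


def voting_ensemble(C: ConfidenceMatrix, threshold: float = 0.5) -> np.ndarray:
    """Majority vote of the hard labels at ``threshold``; with an odd number
    of voters there are no ties."""
    votes = (C.values >= threshold).sum(axis=1)
    return (votes > C.values.shape[1] / 2).astype(int)
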