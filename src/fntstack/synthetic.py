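"""Synthetic compound-descriptor tables for the active/decoy screening task.

The real benchmark this package targets — 88 literature-curated actives
against 264 property-matched decoys described by molecular descriptors — is
not publicly deposited, so this module generates statistically comparable
stand-ins: numeric feature tables with the same 1:3 class imbalance,
configurable dimensionality, and three signal layouts:

``blobs``
    Two Gaussian classes separated by a mean shift on a random informative
    subset; every reasonable classifier does well.
``complementary``
    Three disjoint signal blocks — a weak linear-margin block, an
    XOR-style interaction block invisible to linear models, and a
    local-cluster block favouring neighbourhood methods — plus pure noise.
    No single model family sees all of the signal, which is the regime where
    stacking the nine base learners pays off.
``null``
    Labels independent of all features; the leakage canary.

Descriptor marginals are continuous Gaussians; computing real descriptors
from structures is out of scope — the package consumes feature tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .tree import FlexibleNeuralTree, OperatorNode, VariableNode

STRUCTURES = ("blobs", "complementary", "null")


class SyntheticDataError(ValueError):
    pass


@dataclass
class DatasetSpec:
    """Shape and signal layout of a generated table.

    Defaults mirror the screening benchmark: 88 actives, 264 decoys,
    50 descriptors.
    """

    n_pos: int = 88
    n_neg: int = 264
    m: int = 50
    structure: str = "blobs"
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise SyntheticDataError("both classes need at least one row")
        if self.m < 2:
            raise SyntheticDataError("need at least 2 descriptors")
        if self.structure not in STRUCTURES:
            raise SyntheticDataError(
                f"structure {self.structure!r} not in {STRUCTURES}"
            )
        if self.noise_sd <= 0:
            raise SyntheticDataError("noise_sd must be positive")
        if self.structure == "complementary" and self.m < 13:
            raise SyntheticDataError(
                "complementary structure needs m >= 13 (6 linear + 4 "
                "interaction + 3 cluster features)"
            )


@dataclass
class LabeledTable:
    """Compound feature table with binary activity labels."""

    ids: np.ndarray
    features: np.ndarray
    labels: np.ndarray
    feature_names: Tuple[str, ...]

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if np.isnan(self.features).any():
            raise SyntheticDataError("features contain missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise SyntheticDataError("labels must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, "id", self.ids)
        df["label"] = self.labels
        return df


def _blobs(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_pos + spec.n_neg
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.m))
    n_info = min(10, spec.m)
    informative = rng.choice(spec.m, size=n_info, replace=False)
    X[: spec.n_pos, informative] += 2.5 * spec.noise_sd
    return X


def _complementary(spec: DatasetSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_pos + spec.n_neg
    pos = slice(0, spec.n_pos)
    neg = slice(spec.n_pos, n)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.m))

    # Linear block (features 0..5): weak per-feature mean shift; linear
    # margins integrate it, but no single feature separates.
    X[pos, 0:6] += 0.4 * spec.noise_sd

    # Interaction block (features 6..9): two XOR-style pairs.  Actives sit in
    # the (+,+)/(-,-) quadrants, decoys in (+,-)/(-,+); marginals match, so
    # linear models are blind while axis-splitting trees are not.
    for pair in ((6, 7), (8, 9)):
        for rows, same_sign in ((pos, True), (neg, False)):
            count = rows.stop - rows.start
            s1 = rng.choice([-1.0, 1.0], size=count)
            s2 = s1 if same_sign else -s1
            mag = 1.2 * spec.noise_sd
            X[rows, pair[0]] = s1 * mag + rng.normal(
                0, 0.9 * spec.noise_sd, count
            )
            X[rows, pair[1]] = s2 * mag + rng.normal(
                0, 0.9 * spec.noise_sd, count
            )

    # Cluster block (features 10..12): actives concentrate in a few tight
    # pockets of a broad decoy cloud — a neighbourhood/partition signal.
    centers = rng.normal(0.0, 1.6, size=(4, 3))
    assign = rng.integers(4, size=spec.n_pos)
    X[pos, 10:13] = centers[assign] + rng.normal(
        0, 0.5 * spec.noise_sd, size=(spec.n_pos, 3)
    )
    X[neg, 10:13] = rng.normal(0.0, 1.6, size=(spec.n_neg, 3))
    return X


def generate_dataset(spec: DatasetSpec) -> LabeledTable:
    """Generate a labeled descriptor table; fully determined by the seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    if spec.structure == "blobs":
        X = _blobs(spec, rng)
    elif spec.structure == "complementary":
        X = _complementary(spec, rng)
    else:
        X = rng.normal(0.0, spec.noise_sd, size=(n, spec.m))
    y = np.concatenate(
        [np.ones(spec.n_pos, dtype=int), np.zeros(spec.n_neg, dtype=int)]
    )
    order = rng.permutation(n)
    X, y = X[order], y[order]
    width = len(str(n))
    ids = np.array([f"cmpd{str(i + 1).zfill(width)}" for i in range(n)])
    names = tuple(f"d{j + 1}" for j in range(spec.m))
    return LabeledTable(ids=ids, features=X, labels=y, feature_names=names)


# ---------------------------------------------------------------------------
# Worked fixture: a fixed small tree with hand-computed outputs
# ---------------------------------------------------------------------------

#: Outputs of the fixture tree on the fixture inputs, computed by hand from
#: the Gaussian-operator formula (inner node first, then the root) and
#: frozen here as test anchors.
WORKED_FIXTURE_OUTPUTS = (
    0.9812713521199744,
    0.9995335234621687,
    0.7891725906547057,
    0.9938723829808351,
)


def generate_worked_fixture():
    """A fixed 2-operator / 3-leaf tree plus 4 inputs and their outputs.

    The tree is ``(+2 w=0.6,-0.4 a=0.25 b=0.8 (+2 w=0.5,0.5 a=0.3 b=0.4
    (c1) (c2)) (c3))`` over nine inputs; only ``c1..c3`` matter, the rest
    exercise the implicit input selection of the tree.
    """
    inner = OperatorNode(
        weights=[0.5, 0.5],
        center=0.3,
        width=0.4,
        children=[VariableNode(0), VariableNode(1)],
    )
    root = OperatorNode(
        weights=[0.6, -0.4],
        center=0.25,
        width=0.8,
        children=[inner, VariableNode(2)],
    )
    tree = FlexibleNeuralTree(root, n_inputs=9, max_depth=4)
    inputs = np.array(
        [
            [0.2, 0.4, 0.6, 0.1, 0.9, 0.3, 0.7, 0.5, 0.8],
            [0.9, 0.1, 0.5, 0.2, 0.8, 0.4, 0.6, 0.3, 0.7],
            [0.8, 0.6, 0.9, 0.3, 0.7, 0.5, 0.5, 0.2, 0.6],
            [0.05, 0.15, 0.7, 0.4, 0.6, 0.6, 0.4, 0.1, 0.5],
        ]
    )
    return tree, inputs, WORKED_FIXTURE_OUTPUTS
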