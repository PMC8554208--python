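"""CSV feature-table I/O and the flat key=value config format.

Tables are UTF-8 CSV with a header row: the first column is the compound
id, feature columns are numeric, and the label column (default ``label``)
holds 0/1.  Errors name the offending row and column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .synthetic import LabeledTable


class TableFormatError(ValueError):
    pass


class MissingLabelColumnError(TableFormatError):
    pass


class MissingValueError(TableFormatError):
    pass


class NonNumericFeatureError(TableFormatError):
    pass


def read_feature_table(path, label_column: str = "label") -> LabeledTable:
    """Read a compound feature table; first column is the row id."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 3:
        raise TableFormatError(
            f"{path}: need at least id, one feature and a label column"
        )
    if label_column not in df.columns:
        raise MissingLabelColumnError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    id_column = df.columns[0]
    ids = df[id_column].astype(str).to_numpy()
    feature_cols = [
        c for c in df.columns if c not in (id_column, label_column)
    ]
    for col in feature_cols + [label_column]:
        series = df[col]
        if series.isna().any():
            row = int(series.index[series.isna()][0])
            raise MissingValueError(
                f"{path}: missing value at row {row} (id "
                f"{ids[row]!r}), column {col!r}"
            )
        coerced = pd.to_numeric(series, errors="coerce")
        if coerced.isna().any():
            row = int(series.index[coerced.isna()][0])
            raise NonNumericFeatureError(
                f"{path}: non-numeric value {series.iloc[row]!r} at row "
                f"{row} (id {ids[row]!r}), column {col!r}"
            )
        df[col] = coerced
    labels = df[label_column].to_numpy()
    if not set(np.unique(labels)) <= {0, 1}:
        raise TableFormatError(
            f"{path}: label column {label_column!r} must contain only 0/1"
        )
    return LabeledTable(
        ids=ids,
        features=df[feature_cols].to_numpy(dtype=float),
        labels=labels.astype(int),
        feature_names=tuple(feature_cols),
    )


def write_feature_table(table: LabeledTable, path) -> None:
    """Write a table; reading it back reproduces the values exactly
    (floats are serialized with shortest round-trip repr)."""
    df = table.to_dataframe()
    df.to_csv(path, index=False)


def read_config(path) -> Dict[str, str]:
    """Flat ``key = value`` config file; '#' starts a comment."""
    options: Dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise TableFormatError(
                f"{path}:{lineno}: expected 'key = value', got {raw!r}"
            )
        key, _, value = line.partition("=")
        options[key.strip().replace("-", "_")] = value.strip()
    return options
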