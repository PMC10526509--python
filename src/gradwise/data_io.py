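"""Reading, validating, encoding and normalizing sample-by-feature tables.

The expected input is a delimited text table of samples by features with a
binary class column (e.g. tumor grade LGG vs. GBM).  Features are a mix of
clinical covariates (continuous age, categorical gender/race) and molecular
indicators (0 = gene not mutated, 1 = mutated).  Everything downstream of
loading works on the :class:`FeatureTable` container defined here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

KIND_CONTINUOUS = "continuous"
KIND_BINARY = "binary"
KIND_CATEGORICAL = "categorical"
FEATURE_KINDS = (KIND_CONTINUOUS, KIND_BINARY, KIND_CATEGORICAL)


class SchemaError(ValueError):
    """The file does not have the expected columns."""


class ValidationError(ValueError):
    """The file has the expected shape but invalid content."""


class KindError(ValueError):
    """An operation was applied to a feature of the wrong kind."""


class DegenerateFeatureError(ValueError):
    """A feature is constant where variation is required."""


@dataclass(frozen=True)
class FeatureTable:
    """An in-memory samples-by-features matrix with a binary label.

    Parameters
    ----------
    sample_ids
        Opaque per-row identifiers (row order is meaningful only for
        cross-validation bookkeeping; all statistics are order-invariant).
    feature_names, feature_kinds
        Parallel tuples; kinds are ``continuous``, ``binary`` or
        ``categorical`` (integer-coded levels).
    X
        ``(n, p)`` float matrix. Binary columns contain only 0/1.
    y
        Length-``n`` integer vector in {0, 1}; 1 is the positive class.
    positive_label
        The original label string mapped to 1 (e.g. ``"GBM"``).
    normalized
        Names of columns that have been z-scored, for provenance.
    """

    sample_ids: tuple
    feature_names: tuple
    feature_kinds: tuple
    X: np.ndarray
    y: np.ndarray
    positive_label: str
    normalized: tuple = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        n, p = X.shape
        if p < 2:
            raise ValidationError(f"need at least 2 features, got {p}")
        if len(self.feature_names) != p or len(self.feature_kinds) != p:
            raise ValidationError("feature_names/kinds do not match X width")
        if len(set(self.feature_names)) != p:
            raise ValidationError("feature names are not unique")
        if len(self.sample_ids) != n or y.shape != (n,):
            raise ValidationError("sample_ids/y do not match X height")
        if np.isnan(X).any():
            i, j = np.argwhere(np.isnan(X))[0]
            raise ValidationError(
                f"missing value at row {i}, column {self.feature_names[j]!r}"
            )
        if not set(np.unique(y)) == {0, 1}:
            raise ValidationError("both classes must be present in y")
        for k, name in zip(self.feature_kinds, self.feature_names):
            if k not in FEATURE_KINDS:
                raise ValidationError(f"unknown feature kind {k!r} for {name!r}")
        for j, (k, name) in enumerate(zip(self.feature_kinds, self.feature_names)):
            if k == KIND_BINARY and not np.isin(X[:, j], (0.0, 1.0)).all():
                raise ValidationError(f"binary feature {name!r} has values outside {{0,1}}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def index_of(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError:
            raise KeyError(f"no feature named {name!r}") from None

    def kind_of(self, name: str) -> str:
        return self.feature_kinds[self.index_of(name)]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.index_of(name)]

    def columns(self, names) -> np.ndarray:
        idx = [self.index_of(n) for n in names]
        return self.X[:, idx]

    def take_rows(self, rows) -> "FeatureTable":
        rows = np.asarray(rows)
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in rows),
            X=self.X[rows],
            y=self.y[rows],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "sample_id", list(self.sample_ids))
        df["__label__"] = self.y
        return df


def _infer_kind(col: pd.Series) -> str:
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().all():
        values = set(numeric.unique())
        if values <= {0.0, 1.0}:
            return KIND_BINARY
        if len(values) > 2:
            return KIND_CONTINUOUS
    return KIND_CATEGORICAL


def _encode_column(col: pd.Series, kind: str, name: str) -> np.ndarray:
    if kind in (KIND_BINARY, KIND_CONTINUOUS):
        numeric = pd.to_numeric(col, errors="coerce")
        if numeric.isna().any():
            row = int(numeric.index[numeric.isna()][0])
            raise ValidationError(f"non-numeric value at row {row}, column {name!r}")
        values = numeric.to_numpy(dtype=float)
        if kind == KIND_BINARY and not np.isin(values, (0.0, 1.0)).all():
            raise ValidationError(f"binary feature {name!r} has values outside {{0,1}}")
        return values
    # categorical: integer-code by sorted level order so the encoding does
    # not depend on row order
    levels = sorted(col.astype(str).unique())
    mapping = {lev: i for i, lev in enumerate(levels)}
    return col.astype(str).map(mapping).to_numpy(dtype=float)


def load_feature_table(
    path,
    label_column: str = "Grade",
    positive_label: str = "GBM",
    kind_overrides: dict | None = None,
    id_column: str | None = None,
) -> FeatureTable:
    """Load a CSV into a validated :class:`FeatureTable`.

    Feature kinds are inferred per column: values within {0, 1} are binary,
    numeric columns with more than two distinct values are continuous, and
    everything else is categorical (integer-coded by sorted level order).
    ``kind_overrides`` maps feature name to kind to override the inference.
    The label column must contain exactly two distinct values; rows equal to
    ``positive_label`` become class 1.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if label_column not in df.columns:
        raise SchemaError(f"label column {label_column!r} not found in {path.name}")
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df.index[df[col].isna()][0])
        raise ValidationError(f"missing value at row {row}, column {col!r}")

    labels = df[label_column].astype(str)
    distinct = sorted(labels.unique())
    if len(distinct) != 2:
        raise ValidationError(
            f"label column {label_column!r} must have exactly two classes, got {distinct}"
        )
    if str(positive_label) not in distinct:
        raise ValidationError(
            f"positive label {positive_label!r} not present (classes: {distinct})"
        )
    y = (labels == str(positive_label)).to_numpy(dtype=int)

    if id_column is not None and id_column in df.columns:
        sample_ids = tuple(df[id_column].astype(str))
        feature_cols = [c for c in df.columns if c not in (label_column, id_column)]
    else:
        sample_ids = tuple(range(len(df)))
        feature_cols = [c for c in df.columns if c != label_column]

    overrides = dict(kind_overrides or {})
    names, kinds, columns = [], [], []
    for name in feature_cols:
        kind = overrides.get(name) or _infer_kind(df[name])
        if kind not in FEATURE_KINDS:
            raise ValidationError(f"invalid kind override {kind!r} for {name!r}")
        names.append(name)
        kinds.append(kind)
        columns.append(_encode_column(df[name], kind, name))

    X = np.column_stack(columns)
    return FeatureTable(
        sample_ids=sample_ids,
        feature_names=tuple(names),
        feature_kinds=tuple(kinds),
        X=X,
        y=y,
        positive_label=str(positive_label),
    )


def zscore_continuous(table: FeatureTable, feature_names=None) -> FeatureTable:
    """Standardize continuous columns to zero mean and unit variance.

    Uses the population convention (divide by ``n``) so the transform is
    bit-stable across implementations.  By default every continuous feature
    is standardized; pass explicit names to restrict.  Statistics are taken
    over all rows of ``table``.
    """
    if feature_names is None:
        feature_names = [
            n for n, k in zip(table.feature_names, table.feature_kinds)
            if k == KIND_CONTINUOUS
        ]
    X = table.X.copy()
    for name in feature_names:
        j = table.index_of(name)
        if table.feature_kinds[j] != KIND_CONTINUOUS:
            raise KindError(f"{name!r} is {table.feature_kinds[j]}, not continuous")
        col = X[:, j]
        sd = float(np.std(col))  # population: ddof=0
        if sd == 0.0:
            raise DegenerateFeatureError(f"{name!r} has zero standard deviation")
        X[:, j] = (col - float(np.mean(col))) / sd
    return replace(
        table,
        X=X,
        normalized=tuple(dict.fromkeys(tuple(table.normalized) + tuple(feature_names))),
    )


def write_table_csv(table: FeatureTable, path, label_column: str = "Grade",
                    negative_label: str = "LGG") -> None:
    """Write a FeatureTable back to CSV in the shape ``load_feature_table`` reads."""
    df = pd.DataFrame(table.X, columns=list(table.feature_names))
    # keep binary/categorical columns as integers in the file
    for name, kind in zip(table.feature_names, table.feature_kinds):
        if kind in (KIND_BINARY, KIND_CATEGORICAL):
            df[name] = df[name].astype(int)
    df[label_column] = np.where(table.y == 1, table.positive_label, negative_label)
    df.to_csv(path, index=False)


# Report types and writers live in gradwise.report; re-exported here so the
# I/O surface of the package is a single module.
from .report import SelectionReport, read_report, write_report  # noqa: E402,F401
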