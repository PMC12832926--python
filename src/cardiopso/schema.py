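"""Cohort schema for the 14-attribute UCI heart-disease table.

The composite UCI heart-disease cohort (Cleveland, Statlog, Hungarian,
Switzerland, Long Beach) shares 14 attributes: five continuous
measurements (age, resting blood pressure, serum cholesterol, maximum
heart rate, exercise-induced ST depression), eight integer-coded
categorical/binary attributes, and a binary diagnosis target
(1 = heart disease present).  :data:`DEFAULT_SCHEMA` encodes the
attribute names, kinds, code sets and plausible physical ranges; other
tabular cohorts can be described by constructing a different
:class:`SchemaSpec`.

A *FeatureTable* in this package is a plain :class:`pandas.DataFrame`
validated against a :class:`SchemaSpec`; missing cells are ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = ["ColumnSpec", "SchemaSpec", "DEFAULT_SCHEMA"]

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
BINARY = "binary"
TARGET = "target"


@dataclass(frozen=True)
class ColumnSpec:
    """Description of one cohort column.

    Parameters
    ----------
    name
        Column label.
    kind
        ``"continuous"``, ``"categorical"``, ``"binary"`` or ``"target"``.
    lo, hi
        Plausible physical range for continuous columns (values outside
        are admitted on ingestion but logged — they may be the very
        outliers the pipeline exists to repair).
    codes
        Enumerated integer codes for categorical/binary/target columns.
    """

    name: str
    kind: str
    lo: float | None = None
    hi: float | None = None
    codes: tuple[int, ...] | None = None


@dataclass(frozen=True)
class SchemaSpec:
    """Ordered column specification plus missing-value tokens."""

    columns: tuple[ColumnSpec, ...]
    missing_tokens: tuple[str, ...] = ("", "?", "NA")

    def __post_init__(self) -> None:
        targets = [c.name for c in self.columns if c.kind == TARGET]
        if len(targets) != 1:
            raise SchemaError(f"schema must declare exactly one target column, got {targets}")

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    @property
    def target_name(self) -> str:
        return next(c.name for c in self.columns if c.kind == TARGET)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.kind != TARGET)

    @property
    def continuous_columns(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.kind == CONTINUOUS)

    @property
    def coded_columns(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns if c.kind in (CATEGORICAL, BINARY, TARGET))

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def validate(self, df: pd.DataFrame, allow_missing: bool = True) -> None:
        """Raise :class:`SchemaError` unless ``df`` conforms to this schema.

        Checks column names/order, minimum row count, numeric dtypes,
        categorical code membership and (optionally) the absence of
        missing cells.  Continuous values outside [lo, hi] are *not*
        rejected; repairing them is the preprocessing pipeline's job.
        """
        if tuple(df.columns) != self.column_names:
            raise SchemaError(
                f"column mismatch: expected {list(self.column_names)}, got {list(df.columns)}"
            )
        if len(df) < 1:
            raise SchemaError("table must have at least one row")
        for spec in self.columns:
            col = df[spec.name]
            if not pd.api.types.is_numeric_dtype(col):
                raise SchemaError(f"column {spec.name!r} is not numeric")
            missing = col.isna()
            if not allow_missing and missing.any():
                row = int(np.flatnonzero(missing.to_numpy())[0])
                raise SchemaError(f"missing value in column {spec.name!r} at row {row}")
            if spec.codes is not None:
                observed = col.dropna()
                bad = ~observed.isin(spec.codes)
                if bad.any():
                    row = int(observed.index[np.flatnonzero(bad.to_numpy())[0]])
                    raise SchemaError(
                        f"column {spec.name!r} row {row}: value {observed.loc[row]!r} "
                        f"not in codes {spec.codes}"
                    )


def _heart_columns() -> tuple[ColumnSpec, ...]:
    return (
        ColumnSpec("age", CONTINUOUS, 28, 77),
        ColumnSpec("sex", BINARY, codes=(0, 1)),
        ColumnSpec("cp", CATEGORICAL, codes=(0, 1, 2, 3)),
        ColumnSpec("trestbps", CONTINUOUS, 80, 200),
        ColumnSpec("chol", CONTINUOUS, 85, 603),
        ColumnSpec("restecg", CATEGORICAL, codes=(0, 1, 2)),
        ColumnSpec("fbs", BINARY, codes=(0, 1)),
        ColumnSpec("thalach", CONTINUOUS, 60, 202),
        ColumnSpec("exang", BINARY, codes=(0, 1)),
        ColumnSpec("oldpeak", CONTINUOUS, -2.6, 6.2),
        ColumnSpec("slope", CATEGORICAL, codes=(0, 1, 2)),
        ColumnSpec("ca", CATEGORICAL, codes=(0, 1, 2, 3)),
        ColumnSpec("thal", CATEGORICAL, codes=(0, 1, 2)),
        ColumnSpec("target", TARGET, codes=(0, 1)),
    )


#: The 14-attribute UCI heart-disease schema.
DEFAULT_SCHEMA = SchemaSpec(columns=_heart_columns())
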