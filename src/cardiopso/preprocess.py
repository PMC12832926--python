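"""Robust tabular preprocessing for clinical cohorts.

The refinement suite applies, in a fixed order:

1. **padding (forward-fill) interpolation** — each missing cell takes the
   nearest preceding observed value in its column; fails loudly if a
   column's first value is missing, since there is then nothing to pad
   from;
2. **exact-duplicate removal** — repeated patient records are reduced to
   their first occurrence;
3. **IQR outlier imputation** — values outside the Tukey fences
   ``[Q1 - 1.5*IQR, Q3 + 1.5*IQR]`` are replaced by the column median
   (computed once on the full column before any replacement), applied to
   continuous columns only;
4. **robust scaling** — ``(x - median) / IQR``, resistant to any
   remaining heavy tails; the diagnosis target is never scaled.

Quartiles throughout use linear interpolation between order statistics
(the "type 7" convention, the default of numpy/pandas/R).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, SchemaError
from .schema import DEFAULT_SCHEMA, SchemaSpec

__all__ = [
    "OutlierBounds",
    "ScaleParams",
    "PipelineConfig",
    "PipelineLog",
    "pad_interpolate",
    "drop_duplicates",
    "iqr_bounds",
    "impute_outliers_median",
    "robust_scale",
    "apply_scale",
    "pearson_correlation",
    "run_pipeline",
]

QUARTILE_METHOD = "linear"  # numpy's name for the type-7 convention


@dataclass(frozen=True)
class OutlierBounds:
    """Tukey fences of a numeric column: ``lower = Q1 - 1.5*IQR``,
    ``upper = Q3 + 1.5*IQR``."""

    q1: float
    q3: float
    iqr: float
    lower: float
    upper: float

    @classmethod
    def from_quartiles(cls, q1: float, q3: float) -> "OutlierBounds":
        iqr = q3 - q1
        return cls(q1=q1, q3=q3, iqr=iqr, lower=q1 - 1.5 * iqr, upper=q3 + 1.5 * iqr)

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of values inside (inclusive) the fences."""
        values = np.asarray(values, dtype=float)
        return (values >= self.lower) & (values <= self.upper)


@dataclass(frozen=True)
class ScaleParams:
    """Per-column robust-scaling parameters fitted on a row subset.

    Columns whose fitted IQR is zero cannot be scaled; they are passed
    through unchanged and listed in ``degenerate``.
    """

    median: Mapping[str, float]
    iqr: Mapping[str, float]
    columns: tuple[str, ...]
    degenerate: tuple[str, ...] = ()


def iqr_bounds(column: Sequence[float] | np.ndarray | pd.Series) -> OutlierBounds:
    """Tukey fences of a numeric column under type-7 quartiles.

    Raises
    ------
    DomainError
        If the column is empty or contains missing values.
    """
    values = np.asarray(column, dtype=float)
    if values.size == 0:
        raise DomainError("cannot compute quartiles of an empty column")
    if np.isnan(values).any():
        raise DomainError("column contains missing values; interpolate first")
    q1, q3 = np.quantile(values, [0.25, 0.75], method=QUARTILE_METHOD)
    return OutlierBounds.from_quartiles(float(q1), float(q3))


def pad_interpolate(table: pd.DataFrame) -> pd.DataFrame:
    """Forward-fill missing cells column by column.

    Each missing cell takes the nearest preceding non-missing value in
    its column; observed cells and row order are untouched.

    Raises
    ------
    SchemaError
        If any column's first row is missing (there is no preceding
        value to pad from).
    """
    first = table.iloc[0]
    leading = first.isna()
    if leading.any():
        bad = list(table.columns[leading])
        raise SchemaError(f"leading missing value in column(s) {bad}; padding cannot start")
    return table.ffill()


def drop_duplicates(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Reduce exact-duplicate rows (all columns equal) to their first
    occurrence, preserving the relative order of kept rows.

    Returns the deduplicated table and the number of rows removed.
    """
    out = table.drop_duplicates(keep="first")
    return out, len(table) - len(out)


def impute_outliers_median(
    column: Sequence[float] | np.ndarray | pd.Series,
) -> tuple[np.ndarray, int]:
    """Replace values strictly outside the Tukey fences with the column
    median.

    The median is that of the full input column, computed once before
    any replacement, and always lies inside the fences, so the output
    contains no value outside the input's fences.

    Returns the repaired values and the number of replacements.
    """
    values = np.asarray(column, dtype=float)
    if values.size == 0:
        raise DomainError("cannot impute an empty column")
    bounds = iqr_bounds(values)
    median = float(np.median(values))
    outside = ~bounds.contains(values)
    out = values.copy()
    out[outside] = median
    return out, int(outside.sum())


def robust_scale(
    table: pd.DataFrame,
    fit_on: Sequence[int] | pd.Index | None = None,
    columns: Sequence[str] | None = None,
    target_name: str = "target",
) -> tuple[pd.DataFrame, ScaleParams]:
    """Scale columns to ``(x - median) / IQR`` with parameters estimated
    on ``fit_on`` rows only.

    Parameters
    ----------
    fit_on
        Row labels to estimate median/IQR on.  ``None`` fits on the whole
        table — the protocol of scaling the full cohort before any
        train/test split.  Passing training-row labels instead avoids
        test-set leakage ("safe" mode).
    columns
        Columns to scale; default is every column except ``target_name``.
        The target is never scaled even if listed.

    Columns with zero IQR on the fit rows are passed through unchanged
    and flagged in :attr:`ScaleParams.degenerate`.
    """
    if columns is None:
        columns = [c for c in table.columns if c != target_name]
    else:
        columns = [c for c in columns if c != target_name]
    fit = table if fit_on is None else table.loc[fit_on]
    if len(fit) == 0:
        raise DomainError("fit subset is empty")

    medians: dict[str, float] = {}
    iqrs: dict[str, float] = {}
    degenerate: list[str] = []
    out = table.copy()
    for name in columns:
        col = fit[name].to_numpy(dtype=float)
        q1, q3 = np.quantile(col, [0.25, 0.75], method=QUARTILE_METHOD)
        med = float(np.median(col))
        iqr = float(q3 - q1)
        medians[name] = med
        iqrs[name] = iqr
        if iqr == 0.0:
            degenerate.append(name)
            continue
        out[name] = (table[name].to_numpy(dtype=float) - med) / iqr
    params = ScaleParams(
        median=medians,
        iqr=iqrs,
        columns=tuple(c for c in columns if c not in degenerate),
        degenerate=tuple(degenerate),
    )
    return out, params


def apply_scale(table: pd.DataFrame, params: ScaleParams) -> pd.DataFrame:
    """Apply previously fitted robust-scaling parameters to new rows."""
    out = table.copy()
    for name in params.columns:
        out[name] = (table[name].to_numpy(dtype=float) - params.median[name]) / params.iqr[name]
    return out


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation ``r`` in [-1, 1].

    Raises
    ------
    DomainError
        On length mismatch, fewer than two observations, or a constant
        input (the correlation is then undefined).
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise DomainError(f"length mismatch: {xv.shape} vs {yv.shape}")
    if xv.size < 2:
        raise DomainError("correlation requires at least two observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DomainError("correlation undefined for constant input")
    return float(stats.pearsonr(xv, yv).statistic)


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of :func:`run_pipeline`.

    ``outlier_columns=None`` means the schema's continuous columns —
    Tukey fences on integer category codes are meaningless, so coded
    columns are excluded from outlier repair.  ``scale_columns=None``
    scales every non-target column.  ``scale_fit_rows=None`` fits the
    scaler on all rows (the whole-cohort protocol); pass training-row
    labels for leakage-safe fitting.
    """

    outlier_columns: tuple[str, ...] | None = None
    scale_columns: tuple[str, ...] | None = None
    scale_fit_rows: tuple | None = None


@dataclass
class PipelineLog:
    """Per-stage bookkeeping of one :func:`run_pipeline` call."""

    n_missing_filled: int = 0
    n_duplicates_removed: int = 0
    n_outliers_imputed: int = 0
    outliers_by_column: dict[str, int] = field(default_factory=dict)
    outlier_bounds: dict[str, OutlierBounds] = field(default_factory=dict)
    columns_scaled: tuple[str, ...] = ()
    degenerate_columns: tuple[str, ...] = ()
    quartile_method: str = QUARTILE_METHOD
    stage_order: tuple[str, ...] = (
        "pad_interpolate",
        "drop_duplicates",
        "impute_outliers_median",
        "robust_scale",
    )

    def to_dict(self) -> dict:
        return {
            "n_missing_filled": self.n_missing_filled,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_outliers_imputed": self.n_outliers_imputed,
            "outliers_by_column": dict(self.outliers_by_column),
            "outlier_bounds": {
                k: {"q1": b.q1, "q3": b.q3, "iqr": b.iqr, "lower": b.lower, "upper": b.upper}
                for k, b in self.outlier_bounds.items()
            },
            "columns_scaled": list(self.columns_scaled),
            "degenerate_columns": list(self.degenerate_columns),
            "quartile_method": self.quartile_method,
            "stage_order": list(self.stage_order),
        }


def run_pipeline(
    table: pd.DataFrame,
    config: PipelineConfig | None = None,
    schema: SchemaSpec = DEFAULT_SCHEMA,
) -> tuple[pd.DataFrame, PipelineLog]:
    """Run the full refinement suite in its fixed order:
    interpolate → deduplicate → outlier-impute → robust-scale.

    The column set is conserved and the target column's values are never
    altered.  Returns the refined table and a :class:`PipelineLog` with
    per-stage counts.
    """
    config = config or PipelineConfig()
    schema.validate(table, allow_missing=True)
    log = PipelineLog()

    log.n_missing_filled = int(table.isna().sum().sum())
    out = pad_interpolate(table)

    out, log.n_duplicates_removed = drop_duplicates(out)

    outlier_cols = config.outlier_columns
    if outlier_cols is None:
        outlier_cols = schema.continuous_columns
    for name in outlier_cols:
        log.outlier_bounds[name] = iqr_bounds(out[name])
        repaired, n_imp = impute_outliers_median(out[name])
        out[name] = repaired
        log.outliers_by_column[name] = n_imp
    log.n_outliers_imputed = sum(log.outliers_by_column.values())

    out, params = robust_scale(
        out,
        fit_on=list(config.scale_fit_rows) if config.scale_fit_rows is not None else None,
        columns=list(config.scale_columns) if config.scale_columns is not None else None,
        target_name=schema.target_name,
    )
    log.columns_scaled = params.columns
    log.degenerate_columns = params.degenerate
    return out, log
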