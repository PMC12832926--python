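"""Synthetic clinical cohorts with planted ground truth.

:func:`generate_cohort` draws schema-faithful patient tables: continuous
measurements from truncated normals bounded by the schema's physical
ranges (mid-range mean, range/6 standard deviation), integer-coded
attributes from configurable code frequencies (uniform by default,
except sex which defaults to 76% male, matching the composite cohort's
demographics), and a binary diagnosis from a logistic model over a
designated set of informative features.  The returned truth record
stores the planted coefficients, so feature-selection and
parameter-recovery analyses can be scored against known ground truth.

:func:`corrupt_cohort` then injects the three pathologies the
preprocessing pipeline exists to repair — MCAR missing cells (never in
the first row, so forward-fill always has a value to pad from), exact
duplicate rows, and gross outliers written well outside the Tukey
fences — and returns a cell-level ledger for downstream verification.

By default the per-attribute missingness rates mirror the composite
UCI cohort's observed tallies (e.g. ~17% of slope, ~51% of ca) and the
duplicate fraction its 22.69%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import DomainError
from .schema import DEFAULT_SCHEMA, SchemaSpec

__all__ = [
    "CohortConfig",
    "CohortTruth",
    "CorruptionPlan",
    "CorruptionLedger",
    "generate_cohort",
    "corrupt_cohort",
    "DEFAULT_MISSING_RATES",
]

#: Observed per-attribute missing-value tallies of the 1,190-patient
#: composite cohort, as fractions of its rows.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "trestbps": 60 / 1190,
    "chol": 202 / 1190,
    "fbs": 90 / 1190,
    "restecg": 2 / 1190,
    "thalach": 55 / 1190,
    "exang": 55 / 1190,
    "oldpeak": 62 / 1190,
    "slope": 308 / 1190,
    "ca": 611 / 1190,
    "thal": 479 / 1190,
}

_DEFAULT_INFORMATIVE = ("ca", "thal", "cp", "oldpeak")


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings.

    ``effect_sizes`` are per-feature log-odds coefficients on the
    feature's standardized (z-scored) scale; features not listed in
    ``informative_features`` have zero effect.  ``noise_scale`` is the
    standard deviation of residual logit noise.  The intercept is
    calibrated so the expected positive fraction equals ``prevalence``.
    """

    n_patients: int = 1000
    prevalence: float = 0.5286
    informative_features: tuple[str, ...] = _DEFAULT_INFORMATIVE
    effect_sizes: Mapping[str, float] | None = None
    noise_scale: float = 0.5
    male_fraction: float = 0.76
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise DomainError("n_patients must be >= 1")
        if not (0 < self.prevalence < 1):
            raise DomainError("prevalence must be in (0, 1)")
        if self.noise_scale < 0:
            raise DomainError("noise_scale must be >= 0")

    def resolved_effects(self) -> dict[str, float]:
        if self.effect_sizes is not None:
            return dict(self.effect_sizes)
        return {f: 1.0 for f in self.informative_features}


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a generated cohort."""

    informative_features: tuple[str, ...]
    coefficients: Mapping[str, float]
    intercept: float
    prevalence: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "informative_features": list(self.informative_features),
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "prevalence": self.prevalence,
            "seed": self.seed,
        }


def _draw_column(spec, n: int, rng: np.random.Generator, male_fraction: float) -> np.ndarray:
    if spec.kind == "continuous":
        mean = (spec.lo + spec.hi) / 2.0
        sd = (spec.hi - spec.lo) / 6.0
        # truncated normal by rejection; acceptance is ~99.7%, so a few
        # top-up rounds suffice
        out = np.empty(0)
        while out.size < n:
            draw = rng.normal(mean, sd, size=2 * (n - out.size) + 8)
            draw = draw[(draw >= spec.lo) & (draw <= spec.hi)]
            out = np.concatenate([out, draw])
        values = out[:n]
        if spec.name == "oldpeak":
            return np.round(values, 1)
        return np.round(values).astype(float)
    if spec.name == "sex":
        return rng.binomial(1, male_fraction, size=n).astype(float)
    codes = np.asarray(spec.codes, dtype=float)
    return rng.choice(codes, size=n)


def generate_cohort(
    config: CohortConfig, schema: SchemaSpec = DEFAULT_SCHEMA
) -> tuple[pd.DataFrame, CohortTruth]:
    """Draw a schema-faithful cohort with a planted logistic signal.

    Every generated value respects the schema's declared ranges/codes.
    The target is Bernoulli with logit ``b0 + sum_j beta_j z_j + eps``,
    where ``z_j`` are the informative features z-scored within the
    sample, ``eps ~ Normal(0, noise_scale)``, and ``b0`` is found by
    bisection so the mean predicted probability equals the configured
    prevalence.  Reproducible from ``config.seed``.
    """
    effects = config.resolved_effects()
    unknown = [f for f in effects if f not in schema.feature_names]
    if unknown:
        raise DomainError(f"informative features not in schema: {unknown}")

    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    data = {}
    for spec in schema.columns:
        if spec.kind == "target":
            continue
        data[spec.name] = _draw_column(spec, n, rng, config.male_fraction)

    eta = rng.normal(0.0, config.noise_scale, size=n) if config.noise_scale > 0 else np.zeros(n)
    for name, beta in effects.items():
        col = data[name]
        sd = col.std()
        if sd == 0:
            raise DomainError(f"cannot standardize constant feature {name!r}")
        eta = eta + beta * (col - col.mean()) / sd

    # calibrate the intercept so mean P(target=1) == prevalence
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = (lo + hi) / 2.0
        if expit(mid + eta).mean() < config.prevalence:
            lo = mid
        else:
            hi = mid
    b0 = (lo + hi) / 2.0
    target = rng.binomial(1, expit(b0 + eta)).astype(float)

    df = pd.DataFrame({**data, schema.target_name: target}, columns=list(schema.column_names))
    truth = CohortTruth(
        informative_features=tuple(effects),
        coefficients=effects,
        intercept=b0,
        prevalence=config.prevalence,
        seed=config.seed,
    )
    return df, truth


@dataclass(frozen=True)
class CorruptionPlan:
    """What to inject: per-column missing-cell counts (default: the
    composite cohort's per-attribute rates scaled to this cohort),
    a duplicate fraction, and per-continuous-column outlier counts
    written ``magnitude * IQR`` beyond the Tukey fence."""

    missing_counts: Mapping[str, int] | None = None
    duplicate_fraction: float = 0.2269
    outlier_fraction: float = 0.02
    outlier_magnitude: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.duplicate_fraction):
            raise DomainError("duplicate_fraction must be >= 0")
        if not (0 <= self.outlier_fraction < 1):
            raise DomainError("outlier_fraction must be in [0, 1)")
        if self.outlier_magnitude <= 0:
            raise DomainError("outlier_magnitude must be > 0")

    def resolved_missing_counts(self, n_rows: int) -> dict[str, int]:
        if self.missing_counts is not None:
            return {k: int(v) for k, v in self.missing_counts.items() if v > 0}
        return {
            col: max(1, round(rate * n_rows)) for col, rate in DEFAULT_MISSING_RATES.items()
        }


@dataclass
class CorruptionLedger:
    """Cell-level record of every alteration, for downstream checks.

    ``missing_cells`` and ``outlier_cells`` are ``(row_label, column)``
    pairs; ``duplicate_source_rows`` are the labels of the copied rows
    (one appended copy each).
    """

    missing_cells: list[tuple] = field(default_factory=list)
    outlier_cells: list[tuple] = field(default_factory=list)
    outlier_values: dict[tuple, float] = field(default_factory=dict)
    duplicate_source_rows: list = field(default_factory=list)
    pre_injection_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_missing(self) -> int:
        return len(self.missing_cells)

    @property
    def n_duplicates(self) -> int:
        return len(self.duplicate_source_rows)

    @property
    def n_outliers(self) -> int:
        return len(self.outlier_cells)


def corrupt_cohort(
    table: pd.DataFrame,
    plan: CorruptionPlan,
    schema: SchemaSpec = DEFAULT_SCHEMA,
) -> tuple[pd.DataFrame, CorruptionLedger]:
    """Inject outliers, duplicate rows and missing cells per the plan.

    Order of operations (chosen so pipeline stage counts can be checked
    against the ledger exactly):

    1. gross outliers into continuous columns, at
       ``fence ± magnitude*IQR`` using the pre-injection fences;
    2. exact duplicate rows: ``round(duplicate_fraction * n)`` distinct
       source rows copied, the copies appended in shuffled order;
    3. MCAR missing cells, never in the table's first row and never in
       a source/copy row or an outlier cell — duplicated rows stay
       bit-identical through forward-fill, and every planned pathology
       remains individually observable.

    Raises :class:`DomainError` if the plan is infeasible for the
    cohort's size.
    """
    from .preprocess import iqr_bounds  # local import to avoid a cycle

    rng = np.random.default_rng(plan.seed)
    out = table.copy().reset_index(drop=True)
    n = len(out)
    ledger = CorruptionLedger()

    # -- outliers ------------------------------------------------------
    n_out = round(plan.outlier_fraction * n)
    for col in schema.continuous_columns:
        if n_out == 0:
            break
        b = iqr_bounds(out[col])
        ledger.pre_injection_bounds[col] = (b.lower, b.upper)
        if b.iqr == 0:
            continue
        rows = rng.choice(n, size=n_out, replace=False)
        for r in rows:
            sign = 1 if rng.uniform() < 0.5 else -1
            value = (
                b.upper + plan.outlier_magnitude * b.iqr
                if sign > 0
                else b.lower - plan.outlier_magnitude * b.iqr
            )
            out.iat[int(r), out.columns.get_loc(col)] = value
            ledger.outlier_cells.append((int(r), col))
            ledger.outlier_values[(int(r), col)] = value

    # -- duplicates ----------------------------------------------------
    n_dup = round(plan.duplicate_fraction * n)
    if n_dup > n:
        raise DomainError(f"cannot duplicate {n_dup} rows from a {n}-row cohort")
    if n_dup > 0:
        sources = rng.choice(n, size=n_dup, replace=False)
        copies = out.iloc[sources].copy()
        order = rng.permutation(n_dup)
        copies = copies.iloc[order]
        ledger.duplicate_source_rows = [int(s) for s in sources]
        out = pd.concat([out, copies], ignore_index=True)
    protected_rows = set(ledger.duplicate_source_rows) | set(range(n, len(out))) | {0}

    # -- missing cells -------------------------------------------------
    outlier_set = set(ledger.outlier_cells)
    counts = plan.resolved_missing_counts(n)
    for col, count in counts.items():
        if col not in out.columns:
            raise DomainError(f"missing-plan column {col!r} not in table")
        eligible = [
            r
            for r in range(len(out))
            if r not in protected_rows and (r, col) not in outlier_set
        ]
        if count > len(eligible):
            raise DomainError(
                f"cannot blank {count} cells in {col!r}: only {len(eligible)} eligible rows"
            )
        rows = rng.choice(eligible, size=count, replace=False)
        for r in rows:
            out.iat[int(r), out.columns.get_loc(col)] = np.nan
            ledger.missing_cells.append((int(r), col))

    return out, ledger
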