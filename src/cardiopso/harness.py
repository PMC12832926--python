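"""Experiment orchestration: default and optimizer grids over
train/test ratios, the ablation arms, the paired t-test, and
feature-selection frequency analysis.

Grids evaluate each classifier family at each train/test ratio on a
stratified split (split seed 0 by default).  In optimized modes, the
swarm searches the joint feature-mask/hyperparameter space with
cross-validated F1 computed **on the training portion only**; the best
spec is then refit on the full training portion and scored once on the
untouched test rows.  Every cell records the row labels used on each
side so the absence of test-set leakage is auditable, not assumed.

Scaling is fitted per split on training rows ("safe" mode) unless the
caller asks for the whole-table protocol ("whole" mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import train_test_split

from . import preprocess
from .exceptions import DegenerateVarianceError, DomainError
from .ipso import SwarmConfig, SwarmState, optimize
from .metrics import (
    ConfusionCounts,
    LikelihoodRatios,
    MetricPanel,
    likelihood_ratios,
    metric_panel,
    tally_confusion,
)
from .schema import DEFAULT_SCHEMA, SchemaSpec
from .search import (
    FAMILIES,
    FitnessCache,
    FitnessProtocol,
    ModelSpec,
    build_space,
    decode_particle,
    default_spec,
    fit_final,
)

__all__ = [
    "RATIOS",
    "ExperimentPlan",
    "CellResult",
    "ExperimentReport",
    "TTestResult",
    "stratified_split",
    "run_default_grid",
    "run_optimized_grid",
    "run_ablation",
    "paired_ttest",
    "selection_frequency",
]

#: The three train:test ratios exercised by the experiments.
RATIOS = ("70:30", "80:20", "90:10")


def _train_fraction(ratio: str) -> float:
    try:
        a, b = (int(x) for x in ratio.split(":"))
    except ValueError as exc:
        raise DomainError(f"malformed ratio {ratio!r}; expected 'NN:MM'") from exc
    if a <= 0 or b <= 0:
        raise DomainError(f"ratio parts must be positive, got {ratio!r}")
    return a / (a + b)


@dataclass(frozen=True)
class ExperimentPlan:
    """Which cells to run: ratios x families, in one mode."""

    ratios: tuple[str, ...] = RATIOS
    families: tuple[str, ...] = FAMILIES
    mode: str = "default"  # "default" | "standard-pso" | "ipso"
    split_seed: int = 0
    repeats: int = 10
    scale_fit: str = "safe"  # "safe" | "whole"

    def __post_init__(self) -> None:
        if self.mode not in ("default", "standard-pso", "ipso"):
            raise DomainError(f"unknown mode {self.mode!r}")
        if self.repeats < 1:
            raise DomainError("repeats must be >= 1")
        if self.scale_fit not in ("safe", "whole"):
            raise DomainError(f"unknown scale_fit {self.scale_fit!r}")
        for r in self.ratios:
            _train_fraction(r)


@dataclass
class CellResult:
    """One (family, ratio, mode) evaluation."""

    family: str
    ratio: str
    mode: str
    counts: ConfusionCounts
    panel: MetricPanel
    ratios_panel: LikelihoodRatios
    spec: ModelSpec
    train_rows: tuple = ()
    test_rows: tuple = ()
    history: tuple[float, ...] = ()

    @property
    def leakage_free(self) -> bool:
        """True when no row label appears on both sides of the split."""
        return len(set(self.train_rows) & set(self.test_rows)) == 0

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "ratio": self.ratio,
            "mode": self.mode,
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "panel_percent": self.panel.to_percent(),
            "lr_plus": self.ratios_panel.lr_plus,
            "lr_minus": self.ratios_panel.lr_minus,
            "dor": self.ratios_panel.dor,
            "selected_features": list(self.spec.selected_features),
            "hyperparams": dict(self.spec.hyperparams),
            "leakage_free": self.leakage_free,
            "history": list(self.history),
        }


@dataclass
class ExperimentReport:
    """A grid of cell results plus any attached analyses."""

    mode: str
    cells: list[CellResult] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def cell(self, family: str, ratio: str) -> CellResult:
        for c in self.cells:
            if c.family == family and c.ratio == ratio:
                return c
        raise KeyError((family, ratio))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "cells": [c.to_dict() for c in self.cells],
            "extras": self.extras,
        }


@dataclass(frozen=True)
class TTestResult:
    """Two-sided paired t-test on matched score vectors."""

    t: float
    p: float
    df: int


def stratified_split(
    table: pd.DataFrame,
    ratio: str,
    seed: int = 0,
    target_name: str = "target",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic stratified split at a 'train:test' ratio."""
    frac = _train_fraction(ratio)
    y = table[target_name]
    if y.value_counts().min() < 2:
        raise DomainError("stratified split needs at least two rows per class")
    train, test = train_test_split(
        table, train_size=frac, stratify=y, random_state=seed, shuffle=True
    )
    return train, test


def _scale_for_split(
    train: pd.DataFrame, test: pd.DataFrame, scale_fit: str, target_name: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    if scale_fit == "whole":
        whole = pd.concat([train, test])
        scaled, params = preprocess.robust_scale(whole, target_name=target_name)
        return scaled.loc[train.index], scaled.loc[test.index]
    scaled_train, params = preprocess.robust_scale(train, target_name=target_name)
    return scaled_train, preprocess.apply_scale(test, params)


def _evaluate(
    model, test: pd.DataFrame, target_name: str
) -> tuple[ConfusionCounts, MetricPanel, LikelihoodRatios]:
    pred = model.predict(test)
    counts = tally_confusion(test[target_name].to_numpy(dtype=int), pred)
    return counts, metric_panel(counts, zero_division="zero-with-flag"), likelihood_ratios(counts)


def run_default_grid(
    table: pd.DataFrame,
    plan: ExperimentPlan,
    protocol: FitnessProtocol = FitnessProtocol(),
    schema: SchemaSpec = DEFAULT_SCHEMA,
) -> ExperimentReport:
    """Fit every family with library-default hyperparameters on all
    features, per ratio; the unoptimized baseline grid.

    ``table`` should be refined through the row-level pipeline stages
    but unscaled; scaling is fitted per split according to
    ``plan.scale_fit``.
    """
    if plan.mode != "default":
        raise DomainError("run_default_grid requires plan.mode == 'default'")
    target = schema.target_name
    features = [c for c in table.columns if c != target]
    report = ExperimentReport(mode="default")
    for ratio in plan.ratios:
        train, test = stratified_split(table, ratio, plan.split_seed, target)
        strain, stest = _scale_for_split(train, test, plan.scale_fit, target)
        for family in plan.families:
            spec = default_spec(family, features)
            model = fit_final(spec, strain, protocol, target)
            counts, panel, lrs = _evaluate(model, stest, target)
            report.cells.append(
                CellResult(
                    family=family,
                    ratio=ratio,
                    mode="default",
                    counts=counts,
                    panel=panel,
                    ratios_panel=lrs,
                    spec=spec,
                    train_rows=tuple(train.index),
                    test_rows=tuple(test.index),
                )
            )
    return report


def tune_cell(
    train: pd.DataFrame,
    family: str,
    swarm_config: SwarmConfig,
    protocol: FitnessProtocol = FitnessProtocol(),
    target_name: str = "target",
) -> tuple[ModelSpec, SwarmState]:
    """Swarm-search the joint space on training rows only; returns the
    decoded global-best spec and the swarm state."""
    features = [c for c in train.columns if c != target_name]
    space = build_space(family, features)
    cache = FitnessCache(train, protocol, target_name)

    def fitness(position: np.ndarray) -> float:
        return cache(decode_particle(position, space))

    state = optimize(space, fitness, swarm_config)
    return decode_particle(state.gbest_position, space), state


def run_optimized_grid(
    table: pd.DataFrame,
    plan: ExperimentPlan,
    swarm_config: SwarmConfig,
    protocol: FitnessProtocol = FitnessProtocol(),
    schema: SchemaSpec = DEFAULT_SCHEMA,
) -> ExperimentReport:
    """Swarm-optimized grid: per (family, ratio), search on the training
    portion, refit the winner, evaluate once on the held-out rows.

    ``plan.mode`` selects the engine: ``"ipso"`` uses ``swarm_config``
    as given; ``"standard-pso"`` degrades it to fixed inertia and no
    mutation.
    """
    if plan.mode not in ("standard-pso", "ipso"):
        raise DomainError("run_optimized_grid requires mode 'standard-pso' or 'ipso'")
    config = swarm_config
    if plan.mode == "standard-pso":
        config = SwarmConfig.standard_pso(
            n_particles=swarm_config.n_particles,
            max_iterations=swarm_config.max_iterations,
            c1=swarm_config.c1,
            c2=swarm_config.c2,
            v_max_fraction=swarm_config.v_max_fraction,
            seed=swarm_config.seed,
        )
    target = schema.target_name
    report = ExperimentReport(mode=plan.mode)
    for ratio in plan.ratios:
        train, test = stratified_split(table, ratio, plan.split_seed, target)
        strain, stest = _scale_for_split(train, test, plan.scale_fit, target)
        for family in plan.families:
            spec, state = tune_cell(strain, family, config, protocol, target)
            model = fit_final(spec, strain, protocol, target)
            counts, panel, lrs = _evaluate(model, stest, target)
            report.cells.append(
                CellResult(
                    family=family,
                    ratio=ratio,
                    mode=plan.mode,
                    counts=counts,
                    panel=panel,
                    ratios_panel=lrs,
                    spec=spec,
                    train_rows=tuple(train.index),
                    test_rows=tuple(test.index),
                    history=tuple(state.history),
                )
            )
    return report


def _basic_preprocess(table: pd.DataFrame, target_name: str) -> pd.DataFrame:
    """Ablation arm A's na(i)ve cleanup: mean imputation of missing
    cells plus z-score standardization; no deduplication, no outlier
    handling."""
    out = table.copy()
    for col in out.columns:
        if col == target_name:
            continue
        values = out[col].astype(float)
        values = values.fillna(values.mean())
        sd = values.std(ddof=0)
        out[col] = (values - values.mean()) / sd if sd > 0 else values
    return out


def run_ablation(
    raw_table: pd.DataFrame,
    swarm_config: SwarmConfig,
    protocol: FitnessProtocol = FitnessProtocol(),
    schema: SchemaSpec = DEFAULT_SCHEMA,
    family: str = "XGB",
    ratio: str = "90:10",
    split_seed: int = 0,
) -> list[dict]:
    """Four-arm component ablation at one ratio, on the *raw* (still
    corrupted) table so the preprocessing arms actually differ:

    * **A** — basic preprocessing (mean imputation + standardization),
      default learner;
    * **B** — the full refinement pipeline, default learner;
    * **C** — basic preprocessing + standard-PSO-optimized learner;
    * **D** — the full pipeline + IPSO-optimized learner (the complete
      proposed framework).
    """
    target = schema.target_name
    basic = _basic_preprocess(raw_table, target)
    refined, _log = preprocess.run_pipeline(raw_table, schema=schema)

    std_config = SwarmConfig.standard_pso(
        n_particles=swarm_config.n_particles,
        max_iterations=swarm_config.max_iterations,
        seed=swarm_config.seed,
    )
    arms = [
        ("A", basic, "default", None),
        ("B", refined, "default", None),
        ("C", basic, "optimized", std_config),
        ("D", refined, "optimized", swarm_config),
    ]
    rows = []
    features_of = lambda df: [c for c in df.columns if c != target]
    for label, data, kind, config in arms:
        train, test = stratified_split(data, ratio, split_seed, target)
        if kind == "default":
            spec = default_spec(family, features_of(data))
        else:
            spec, _state = tune_cell(train, family, config, protocol, target)
        model = fit_final(spec, train, protocol, target)
        counts, panel, lrs = _evaluate(model, test, target)
        rows.append(
            {
                "arm": label,
                "accuracy_pct": panel.to_percent()["accuracy"],
                "f1_pct": panel.to_percent()["f1"],
                "dor": lrs.dor,
                "counts": counts,
                "spec": spec,
            }
        )
    return rows


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float]) -> TTestResult:
    """Two-sided paired t-test of matched score vectors.

    ``t = mean(d) / (sd(d) / sqrt(n))`` with ``d = a - b``,
    ``df = n - 1``, and the p-value from the t distribution.

    Raises
    ------
    DegenerateVarianceError
        If the differences have zero variance (the statistic is
        undefined), including the all-identical-differences case.
    DomainError
        On length mismatch or fewer than two pairs.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DomainError("paired t-test needs equal-length 1-D score vectors")
    if a.size < 2:
        raise DomainError("paired t-test needs at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateVarianceError("differences have zero variance")
    n = d.size
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, p=p, df=n - 1)


def selection_frequency(
    runs: Sequence[ModelSpec], feature_labels: Sequence[str] | None = None
) -> dict[str, float]:
    """Per-feature fraction of runs whose mask selected it."""
    if len(runs) == 0:
        raise DomainError("selection_frequency needs at least one run")
    if feature_labels is None:
        feature_labels = sorted({f for spec in runs for f in spec.selected_features})
    return {
        label: sum(label in spec.selected_features for spec in runs) / len(runs)
        for label in feature_labels
    }
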