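"""Joint feature-selection and hyperparameter search spaces for the five
classifier families (LR, LDA, GNB, SVC, XGB).

A particle's normalized position encodes, in order, one binary-like mask
dimension per candidate feature (>= 0.5 means selected) followed by the
family's hyperparameter dimensions.  Decoding maps each hyperparameter
dimension affinely onto its native range — in log10 space for scale
parameters, rounded half-up for integer counts.  An all-zero mask is
repaired by selecting the single highest-valued mask dimension, so a
decoded model always consumes at least one feature.

Fitness is the mean positive-class F1 over stratified k-fold
cross-validation (per-fold F1, then averaged), the balanced
precision/recall objective the swarm maximizes.

The learners themselves are the established scikit-learn and XGBoost
implementations; this module only wires them to the optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .exceptions import DomainError

__all__ = [
    "FAMILIES",
    "Dimension",
    "SearchSpace",
    "ModelSpec",
    "FitnessProtocol",
    "FittedModel",
    "build_space",
    "decode_particle",
    "default_spec",
    "cv_fitness",
    "fit_final",
    "FitnessCache",
]

FAMILIES = ("LR", "LDA", "GNB", "SVC", "XGB")


@dataclass(frozen=True)
class Dimension:
    """One search dimension: a feature-mask bit or a hyperparameter.

    ``kind`` is one of ``mask``, ``continuous``, ``log``, ``integer``,
    ``categorical``; ``low``/``high`` bound numeric kinds, ``levels``
    enumerates categorical ones.
    """

    name: str
    kind: str
    low: float | None = None
    high: float | None = None
    levels: tuple | None = None


# Versioned default hyperparameter spaces, one per family.  Scale-type
# parameters (regularization strengths, kernel width, learning rate) are
# searched in log10 space.
_HYPER_SPACES: dict[str, tuple[Dimension, ...]] = {
    "LR": (Dimension("C", "log", 1e-3, 1e3),),
    "LDA": (Dimension("shrinkage", "continuous", 0.0, 1.0),),
    "GNB": (Dimension("var_smoothing_exponent", "continuous", -12.0, -3.0),),
    "SVC": (
        Dimension("C", "log", 1e-3, 1e3),
        Dimension("gamma", "log", 1e-3, 1e3),
    ),
    "XGB": (
        Dimension("n_estimators", "integer", 50, 500),
        Dimension("max_depth", "integer", 2, 10),
        Dimension("learning_rate", "log", 1e-3, 0.5),
        Dimension("subsample", "continuous", 0.5, 1.0),
        Dimension("colsample_bytree", "continuous", 0.5, 1.0),
    ),
}


@dataclass(frozen=True)
class SearchSpace:
    """Mask dimensions (one per candidate feature, in order) followed by
    the family's hyperparameter dimensions."""

    family: str
    feature_labels: tuple[str, ...]
    hyper_dims: tuple[Dimension, ...]

    @property
    def n_mask(self) -> int:
        return len(self.feature_labels)

    @property
    def n_dims(self) -> int:
        return self.n_mask + len(self.hyper_dims)


@dataclass(frozen=True)
class ModelSpec:
    """A decoded candidate: family, selected features, hyperparameters.

    Hashable, so identical decodings (common for integer/categorical
    collisions) can share cached fitness evaluations.
    """

    family: str
    selected_features: tuple[str, ...]
    hyperparams: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DomainError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if len(self.selected_features) == 0:
            raise DomainError("a model spec must select at least one feature")

    @property
    def params(self) -> dict[str, float]:
        return dict(self.hyperparams)


@dataclass(frozen=True)
class FitnessProtocol:
    """How candidate models are scored: stratified k-fold CV, scorer
    fixed to the positive-class F1."""

    k_folds: int = 5
    eval_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise DomainError("k_folds must be >= 2")


def build_space(family: str, feature_labels: Sequence[str]) -> SearchSpace:
    """The documented default search space for ``family`` plus one mask
    dimension per candidate feature."""
    if family not in _HYPER_SPACES:
        raise DomainError(f"unknown family {family!r}; expected one of {FAMILIES}")
    return SearchSpace(
        family=family,
        feature_labels=tuple(feature_labels),
        hyper_dims=_HYPER_SPACES[family],
    )


def _decode_dim(u: float, dim: Dimension) -> float:
    if dim.kind == "continuous":
        return dim.low + u * (dim.high - dim.low)
    if dim.kind == "log":
        lo, hi = math.log10(dim.low), math.log10(dim.high)
        return 10.0 ** (lo + u * (hi - lo))
    if dim.kind == "integer":
        return int(min(dim.high, max(dim.low, math.floor(dim.low + u * (dim.high - dim.low) + 0.5))))
    if dim.kind == "categorical":
        k = len(dim.levels)
        return dim.levels[min(int(u * k), k - 1)]
    raise DomainError(f"unknown dimension kind {dim.kind!r}")


def decode_particle(position: Sequence[float], space: SearchSpace) -> ModelSpec:
    """Map a normalized position vector to a concrete :class:`ModelSpec`.

    Mask entries >= 0.5 select their feature; an empty mask is repaired
    to the argmax mask entry (first index on ties).
    """
    pos = np.asarray(position, dtype=float)
    if pos.shape != (space.n_dims,):
        raise DomainError(f"position length {pos.shape} != space dimension ({space.n_dims},)")
    mask = pos[: space.n_mask] >= 0.5
    if not mask.any():
        mask[int(np.argmax(pos[: space.n_mask]))] = True
    selected = tuple(lbl for lbl, m in zip(space.feature_labels, mask) if m)
    hyper = tuple(
        (dim.name, _decode_dim(float(u), dim))
        for u, dim in zip(pos[space.n_mask :], space.hyper_dims)
    )
    return ModelSpec(family=space.family, selected_features=selected, hyperparams=hyper)


def default_spec(family: str, feature_labels: Sequence[str]) -> ModelSpec:
    """All features, library-default hyperparameters — the unoptimized
    baseline arm."""
    if family not in FAMILIES:
        raise DomainError(f"unknown family {family!r}")
    return ModelSpec(family=family, selected_features=tuple(feature_labels))


def _make_estimator(spec: ModelSpec, seed: int):
    p = spec.params
    if spec.family == "LR":
        return LogisticRegression(C=p.get("C", 1.0), max_iter=2000, random_state=seed)
    if spec.family == "LDA":
        if "shrinkage" in p:
            return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=p["shrinkage"])
        return LinearDiscriminantAnalysis()
    if spec.family == "GNB":
        if "var_smoothing_exponent" in p:
            return GaussianNB(var_smoothing=10.0 ** p["var_smoothing_exponent"])
        return GaussianNB()
    if spec.family == "SVC":
        return SVC(
            C=p.get("C", 1.0),
            gamma=p.get("gamma", "scale"),
            kernel="rbf",
            random_state=seed,
        )
    if spec.family == "XGB":
        return XGBClassifier(
            n_estimators=int(p.get("n_estimators", 100)),
            max_depth=int(p["max_depth"]) if "max_depth" in p else None,
            learning_rate=p.get("learning_rate"),
            subsample=p.get("subsample"),
            colsample_bytree=p.get("colsample_bytree"),
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
        )
    raise DomainError(f"unknown family {spec.family!r}")


def _xy(table: pd.DataFrame, spec: ModelSpec, target_name: str):
    missing = [f for f in spec.selected_features if f not in table.columns]
    if missing:
        raise DomainError(f"selected features absent from table: {missing}")
    X = table.loc[:, list(spec.selected_features)].to_numpy(dtype=float)
    y = table[target_name].to_numpy(dtype=int)
    return X, y


def cv_fitness(
    spec: ModelSpec,
    table: pd.DataFrame,
    protocol: FitnessProtocol = FitnessProtocol(),
    target_name: str = "target",
) -> float:
    """Mean positive-class F1 over stratified k-fold CV, restricted to
    the spec's selected features; deterministic given ``eval_seed``.

    F1 on a fold with no positive predictions and no positives follows
    the zero-division-to-zero convention.
    """
    X, y = _xy(table, spec, target_name)
    if len(np.unique(y)) < 2:
        raise DomainError("cross-validated fitness requires both classes present")
    skf = StratifiedKFold(
        n_splits=protocol.k_folds, shuffle=True, random_state=protocol.eval_seed
    )
    scores = []
    for train_idx, val_idx in skf.split(X, y):
        est = _make_estimator(spec, protocol.eval_seed)
        est.fit(X[train_idx], y[train_idx])
        pred = est.predict(X[val_idx])
        scores.append(f1_score(y[val_idx], pred, pos_label=1, zero_division=0))
    return float(np.mean(scores))


@dataclass
class FittedModel:
    """A trained predictor bound to its spec and feature subset."""

    spec: ModelSpec
    estimator: object
    target_name: str = "target"

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = table.loc[:, list(self.spec.selected_features)].to_numpy(dtype=float)
        return np.asarray(self.estimator.predict(X), dtype=int)

    def scores(self, table: pd.DataFrame) -> np.ndarray:
        """Continuous scores for ROC analysis: positive-class
        probability where available, otherwise the decision function."""
        X = table.loc[:, list(self.spec.selected_features)].to_numpy(dtype=float)
        if hasattr(self.estimator, "predict_proba"):
            return np.asarray(self.estimator.predict_proba(X))[:, 1]
        return np.asarray(self.estimator.decision_function(X))


def fit_final(
    spec: ModelSpec,
    train: pd.DataFrame,
    protocol: FitnessProtocol = FitnessProtocol(),
    target_name: str = "target",
) -> FittedModel:
    """Fit the spec's learner on the full training table (selected
    features only), seeding any learner RNG from the protocol seed."""
    X, y = _xy(train, spec, target_name)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise DomainError("training data needs at least two rows of each class")
    est = _make_estimator(spec, protocol.eval_seed)
    est.fit(X, y)
    return FittedModel(spec=spec, estimator=est, target_name=target_name)


class FitnessCache:
    """Memoize :func:`cv_fitness` by decoded :class:`ModelSpec`.

    Integer and mask dimensions make distinct particle positions decode
    to identical specs; caching avoids refitting those."""

    def __init__(
        self,
        table: pd.DataFrame,
        protocol: FitnessProtocol = FitnessProtocol(),
        target_name: str = "target",
    ):
        self.table = table
        self.protocol = protocol
        self.target_name = target_name
        self._cache: dict[ModelSpec, float] = {}
        self.n_misses = 0

    def __call__(self, spec: ModelSpec) -> float:
        if spec not in self._cache:
            self.n_misses += 1
            self._cache[spec] = cv_fitness(spec, self.table, self.protocol, self.target_name)
        return self._cache[spec]
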