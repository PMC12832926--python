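"""Clinical diagnostic-accuracy metrics from binary confusion counts.

Beyond the usual machine-learning panel (accuracy, sensitivity,
specificity, precision, F1, NPV, MCC, balanced accuracy, the error rates
FNR/FPR/FDR/FOR, bookmaker informedness and markedness), this module
computes the clinical meta-analytic trio:

* ``LR+ = TPR / FPR`` — how much a positive call raises disease odds,
* ``LR- = FNR / TNR`` — how much a negative call lowers them,
* ``DOR = LR+ / LR- = (TP*TN) / (FP*FN)`` — a single-number summary of
  discriminative power.

All internal arithmetic is full precision; percentages are rounded
(half-up) only at report time via :func:`round_half_up`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import DomainError

__all__ = [
    "ConfusionCounts",
    "MetricPanel",
    "LikelihoodRatios",
    "tally_confusion",
    "metric_panel",
    "likelihood_ratios",
    "roc_auc",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at ``ndigits`` decimals, the
    convention of printed clinical tables (0.915 -> 0.92)."""
    if math.isinf(x) or math.isnan(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN tallies of a binary diagnostic test
    (positive = disease present)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise DomainError(f"{f.name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise DomainError("confusion counts must cover at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def n_positive(self) -> int:
        """Condition-positive count TP + FN."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        """Condition-negative count TN + FP."""
        return self.tn + self.fp

    def swapped(self) -> "ConfusionCounts":
        """Counts under the opposite positive-label convention."""
        return ConfusionCounts(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclass(frozen=True)
class MetricPanel:
    """Proportion-scale metric panel; multiply by 100 for percentages.

    ``flags`` lists metrics that hit an undefined ratio and were set to
    zero under the ``zero-with-flag`` policy.
    """

    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    npv: float
    mcc: float
    fnr: float
    fpr: float
    fdr: float
    for_rate: float
    bm: float
    mk: float
    flags: tuple[str, ...] = ()

    def to_percent(self, ndigits: int = 2) -> dict[str, float]:
        """Panel as half-up-rounded percentages (MCC/BM/MK included)."""
        out = {}
        for f in fields(self):
            if f.name == "flags":
                continue
            out[f.name] = round_half_up(getattr(self, f.name) * 100.0, ndigits)
        return out


@dataclass(frozen=True)
class LikelihoodRatios:
    """Positive/negative likelihood ratios and the diagnostic odds
    ratio; ``inf`` values are flagged, never silently corrected."""

    lr_plus: float
    lr_minus: float
    dor: float
    flags: tuple[str, ...] = ()


def tally_confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from {0,1} label vectors (1 = disease)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1:
        raise DomainError(f"label vectors must be equal-length 1-D, got {t.shape} vs {p.shape}")
    if t.size < 1:
        raise DomainError("label vectors must be non-empty")
    for name, v in (("y_true", t), ("y_pred", p)):
        if not np.isin(v, (0, 1)).all():
            raise DomainError(f"{name} contains labels outside {{0, 1}}")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str, policy: str, flags: list[str]) -> float:
    if den != 0:
        return num / den
    if policy == "error":
        raise DomainError(f"{name} undefined: zero denominator")
    flags.append(name)
    return 0.0


def metric_panel(c: ConfusionCounts, zero_division: str = "error") -> MetricPanel:
    """Evaluate the full metric panel from confusion counts.

    ``zero_division`` governs undefined ratios (e.g. precision with
    TP + FP = 0): ``"error"`` raises :class:`DomainError`;
    ``"zero-with-flag"`` substitutes 0 and records the metric name in
    :attr:`MetricPanel.flags`.
    """
    if zero_division not in ("error", "zero-with-flag"):
        raise ValueError(f"unknown zero_division policy {zero_division!r}")
    flags: list[str] = []
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn

    accuracy = (tp + tn) / c.total
    sensitivity = _ratio(tp, tp + fn, "sensitivity", zero_division, flags)
    specificity = _ratio(tn, tn + fp, "specificity", zero_division, flags)
    precision = _ratio(tp, tp + fp, "precision", zero_division, flags)
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1", zero_division, flags)
    npv = _ratio(tn, tn + fn, "npv", zero_division, flags)
    mcc_den = math.sqrt((tn + fn) * (tp + fp) * (tn + fp) * (fn + tp))
    if mcc_den == 0:
        if zero_division == "error":
            raise DomainError("mcc undefined: a margin of the confusion matrix is zero")
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tn * tp - fp * fn) / mcc_den
    return MetricPanel(
        accuracy=accuracy,
        balanced_accuracy=(sensitivity + specificity) / 2.0,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
        npv=npv,
        mcc=mcc,
        fnr=1.0 - sensitivity,
        fpr=1.0 - specificity,
        fdr=1.0 - precision,
        for_rate=1.0 - npv,
        bm=sensitivity + specificity - 1.0,
        mk=precision + npv - 1.0,
        flags=tuple(flags),
    )


def likelihood_ratios(c: ConfusionCounts, haldane: bool = False) -> LikelihoodRatios:
    """LR+, LR- and DOR from confusion counts.

    A zero FP or FN cell makes LR+ or DOR infinite; these are reported
    as ``inf`` with a flag.  ``haldane=True`` opts into the classical
    +0.5 continuity correction on every cell instead.

    Raises
    ------
    DomainError
        If a condition class is entirely absent (TP + FN = 0 or
        TN + FP = 0), where the rates themselves are undefined.
    """
    if c.n_positive == 0 or c.n_negative == 0:
        raise DomainError("likelihood ratios require both condition classes present")
    tp, tn, fp, fn = (float(x) for x in (c.tp, c.tn, c.fp, c.fn))
    if haldane:
        tp, tn, fp, fn = tp + 0.5, tn + 0.5, fp + 0.5, fn + 0.5
    tpr = tp / (tp + fn)
    fnr = fn / (tp + fn)
    tnr = tn / (tn + fp)
    fpr = fp / (tn + fp)

    flags: list[str] = []
    if fpr == 0:
        lr_plus = math.inf
        flags.append("lr_plus")
    else:
        lr_plus = tpr / fpr
    if tnr == 0:
        lr_minus = math.inf
        flags.append("lr_minus")
    else:
        lr_minus = fnr / tnr
    if lr_minus == 0 or math.isinf(lr_plus):
        dor = math.inf
        flags.append("dor")
    elif math.isinf(lr_minus):
        dor = 0.0
        flags.append("dor")
    else:
        dor = lr_plus / lr_minus
    return LikelihoodRatios(lr_plus=lr_plus, lr_minus=lr_minus, dor=dor, flags=tuple(flags))


def roc_auc(
    scores: Sequence[float], y_true: Sequence[int]
) -> tuple[float, np.ndarray, np.ndarray]:
    """Area under the ROC curve plus the (FPR, TPR) staircase.

    The AUC equals the probability that a random positive outscores a
    random negative, ties counting one half.

    Raises
    ------
    DomainError
        If only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y_true)
    if s.shape != t.shape or s.ndim != 1:
        raise DomainError("scores and labels must be equal-length 1-D vectors")
    if len(np.unique(t)) < 2:
        raise DomainError("ROC undefined with a single class")
    auc = float(roc_auc_score(t, s))
    fpr, tpr, _ = roc_curve(t, s)
    return auc, fpr, tpr
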