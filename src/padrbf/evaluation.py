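"""Binary-classification performance indicators and calibration.

Implements the standard confusion-matrix indicator suite (accuracy,
sensitivity, specificity, PPV, NPV, F-score, Youden index), the ROC curve
with trapezoidal AUC, Youden-optimal cutoff selection, the Hosmer-Lemeshow
chi-square calibration statistic over deciles of predicted risk, and the
mean / SD / 95 % normal-approximation confidence interval summaries used to
report cross-validation folds.

Conventions fixed here and used everywhere else in the package:

* the positive condition is the surgical decision (+1), so "sensitivity" is
  the surgical-detection rate;
* the classification rule at threshold t is p >= t -> positive (closed on
  the left), which makes the ROC endpoints exact;
* indicators with a zero denominator are flagged as NaN rather than raising.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dataclass_fields

import numpy as np

from .errors import UndefinedROCError

#: IndicatorSet fields in report row order.
INDICATOR_NAMES = (
    "auc", "cutoff", "accuracy", "sensitivity", "specificity",
    "ppv", "npv", "f_score", "youden", "hl_statistic",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    """tp/fp/fn/tn counts with the operation class (+1) as positive."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class IndicatorSet:
    """One evaluation's indicators; NaN marks an undefined (0/0) entry."""

    accuracy: float = math.nan
    sensitivity: float = math.nan
    specificity: float = math.nan
    ppv: float = math.nan
    npv: float = math.nan
    f_score: float = math.nan
    youden: float = math.nan
    auc: float = math.nan
    cutoff: float = math.nan
    hl_statistic: float = math.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


@dataclass(frozen=True)
class FoldSummary:
    """Per-indicator mean, SD and 95 % CI over k folds."""

    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_folds: int


def confusion(labels, predictions, positive_label: int = 1) -> ConfusionMatrix:
    """Count tp/fp/fn/tn with the given positive label (+1 = operation)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if labels.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    pos = labels == positive_label
    pred_pos = predictions == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def f_score(sensitivity: float, ppv: float) -> float:
    """Harmonic combination 2 * Sens * PPV / (Sens + PPV)."""
    if sensitivity + ppv == 0 or math.isnan(sensitivity) or math.isnan(ppv):
        return math.nan
    return 2.0 * sensitivity * ppv / (sensitivity + ppv)


def youden_index(sensitivity: float, specificity: float) -> float:
    """Youden's J = sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def indicators(cm: ConfusionMatrix) -> IndicatorSet:
    """The confusion-matrix indicator suite; 0/0 entries come back NaN."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.tn + cm.fp)
    ppv = _ratio(cm.tp, cm.tp + cm.fp)
    return IndicatorSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        f_score=f_score(sens, ppv),
        youden=youden_index(sens, spec),
    )


@dataclass(frozen=True)
class RocCurve:
    """ROC points ordered from (0, 0) to (1, 1) with their thresholds."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_curve(probs, labels) -> RocCurve:
    """Sweep thresholds {0} | {unique scores} | {1 + eps}, highest first.

    At each threshold t the rule p >= t calls a sample positive; the curve
    therefore starts at (0, 0) (nothing called) and ends at (1, 1)
    (everything called).  Requires both classes present.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedROCError("ROC needs at least one sample of each class")

    eps = 1e-9
    thresholds = np.unique(np.concatenate([[0.0], probs, [1.0 + eps]]))[::-1]
    pos_scores = probs[labels == 1]
    neg_scores = probs[labels == -1]
    tpr = np.array([np.sum(pos_scores >= t) / n_pos for t in thresholds])
    fpr = np.array([np.sum(neg_scores >= t) / n_neg for t in thresholds])
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def auc(roc: RocCurve) -> float:
    """Trapezoidal area under the ROC; equals the Mann-Whitney estimate."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def optimal_cutoff(roc: RocCurve) -> float:
    """Threshold maximizing Youden's J; ties go to the smallest threshold."""
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    # thresholds are descending, so the last tied index is the smallest one
    return float(roc.thresholds[best[-1]])


def hosmer_lemeshow(probs, labels, n_groups: int = 10) -> float:
    """Hosmer-Lemeshow chi-square over quantile groups of predicted risk.

    Samples are sorted by predicted probability and split into ``n_groups``
    near-equal groups ("deciles of risk" at the default 10).  Each group
    contributes (O1-E1)^2/E1 + (O0-E0)^2/E0 with E1 the sum of predicted
    probabilities in the group.  Scores clipped to exactly 0 or 1 can make
    an expected count vanish; such denominators (below 1e-10) are replaced
    by a continuity floor of 0.5 expected counts, so a perfectly confident,
    perfectly correct group contributes 0 (not 0/0) and a perfectly
    confident wrong one contributes a large finite penalty.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("Hosmer-Lemeshow needs both classes present")
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if len(probs) < n_groups:
        warnings.warn(
            f"only {len(probs)} samples for {n_groups} groups; "
            f"reducing to {len(probs)} groups"
        )
        n_groups = len(probs)

    order = np.argsort(probs, kind="stable")

    def _den(e: float) -> float:
        return e if e >= 1e-10 else 0.5

    stat = 0.0
    for group in np.array_split(order, n_groups):
        n_g = len(group)
        e1 = float(np.sum(probs[group]))
        e0 = n_g - e1
        o1 = float(np.sum(labels[group] == 1))
        o0 = n_g - o1
        stat += (o1 - e1) ** 2 / _den(e1)
        stat += (o0 - e0) ** 2 / _den(e0)
    return stat


def confidence_interval(mean: float, sd: float, k: int) -> tuple[float, float]:
    """95 % normal-approximation CI for a k-fold mean: mean +/- 1.96 sd/sqrt(k)."""
    half = 1.96 * sd / math.sqrt(k)
    return mean - half, mean + half


def summarize_folds(values) -> FoldSummary:
    """Mean, sample SD and 95 % CI of per-fold indicator values.

    NaN folds (undefined indicators) are dropped with a warning; at least two
    defined folds are required.
    """
    values = np.asarray(values, dtype=float)
    defined = values[~np.isnan(values)]
    if len(defined) < len(values):
        warnings.warn(
            f"dropping {len(values) - len(defined)} undefined fold value(s)"
        )
    if len(defined) < 2:
        raise ValueError("need at least 2 defined fold values to summarize")
    mean = float(np.mean(defined))
    sd = float(np.std(defined, ddof=1))
    lo, hi = confidence_interval(mean, sd, len(defined))
    return FoldSummary(mean=mean, sd=sd, ci_low=lo, ci_high=hi,
                       n_folds=len(defined))
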