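"""Cross-validation harness, hidden-node selection and model comparison.

The evaluation protocol is stratified 10-fold cross-validation: the cohort is
partitioned into 10 folds with approximately equal class composition; each
fold in turn serves as the validation set for a network trained on the other
nine.  Per fold, validation scores yield the ROC, its AUC, the
Youden-optimal cutoff, the thresholded confusion-matrix indicators, and the
Hosmer-Lemeshow statistic.  The number of hidden nodes is selected by
sweeping candidate center counts (2..50 by default) and picking the count
with the smallest mean validation MSE of the raw -1/+1-target scores.  Two
models' per-fold indicator vectors are compared with two-tailed t-tests at
alpha = 0.05 (pooled-variance unpaired by default, paired optionally).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import rbf_network as rbf
from .errors import InfeasibleKError, PadRbfError
from .evaluation import (
    INDICATOR_NAMES,
    FoldSummary,
    IndicatorSet,
    auc,
    confusion,
    hosmer_lemeshow,
    indicators,
    optimal_cutoff,
    roc_curve,
    summarize_folds,
)


@dataclass(frozen=True)
class FoldPlan:
    """A stratified partition: per-sample fold index in ``assignment``."""

    k: int
    assignment: np.ndarray
    seed: int | None = None

    def train_val_indices(self, fold: int):
        val = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, val


@dataclass(frozen=True)
class RBFConfig:
    """Training configuration shared by all folds of one evaluation."""

    n_hidden: int = 29
    eta: float = 0.6
    kmeans_mode: str = "batch"
    tol: float = 1e-6
    max_iter: int = 300
    seed: int = 0


@dataclass(frozen=True)
class SweepResult:
    center_counts: list
    mse_per_count: list
    best_count: int


@dataclass(frozen=True)
class ComparisonRow:
    indicator: str
    summary_a: FoldSummary
    summary_b: FoldSummary
    t_statistic: float
    p_value: float
    significant: bool


def _child_seed(seed: int | None, *keys: int) -> int:
    """Deterministic per-fold/per-count seed derivation, kept below 2**31."""
    ss = np.random.SeedSequence([0 if seed is None else seed, *keys])
    return int(ss.generate_state(1)[0] % (2**31))


def stratified_kfold(labels, k: int = 10, seed: int | None = None) -> FoldPlan:
    """Partition samples into k folds with per-class counts differing by <= 1.

    Within each class the (seeded) shuffled indices are dealt round-robin to
    the folds, so every class contributes floor or ceil of n_class/k samples
    to each fold.  Requires every class to have at least k members.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=int)
    start = 0  # rotate the dealing offset so leftover samples spread evenly
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise ValueError(
                f"class {cls} has {len(idx)} members, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        assignment[idx] = (start + np.arange(len(idx))) % k
        start = (start + len(idx)) % k
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def _evaluate_fold(net, X_val, y_val) -> IndicatorSet:
    probs = rbf.predict_prob(net, X_val)
    roc = roc_curve(probs, y_val)
    preds = rbf.predict_class(net, X_val)
    out = indicators(confusion(y_val, preds))
    out.auc = auc(roc)
    out.cutoff = net.cutoff
    out.hl_statistic = hosmer_lemeshow(probs, y_val)
    return out


def cross_validate(config: RBFConfig, X, y, plan: FoldPlan) -> list[IndicatorSet]:
    """Train/validate once per fold; returns one IndicatorSet per fold.

    The decision cutoff is part of the fitted model: after the weight solve,
    each fold's network replaces its default 0.5 cutoff by the Youden-optimal
    cutoff of its *training* ROC, and the validation fold is classified at
    that frozen cutoff.  (Choosing the cutoff on the validation fold itself
    would optimistically bias the thresholded indicators -- under a null
    cohort the accuracy would sit well above the majority rate.)  AUC and the
    Hosmer-Lemeshow statistic are computed from the validation scores.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    results = []
    for fold in range(plan.k):
        train_idx, val_idx = plan.train_val_indices(fold)
        try:
            net = rbf.train(
                X[train_idx], y[train_idx],
                n_hidden=config.n_hidden, eta=config.eta,
                seed=_child_seed(config.seed, fold),
                kmeans_mode=config.kmeans_mode,
                tol=config.tol, max_iter=config.max_iter,
            )
            train_probs = rbf.predict_prob(net, X[train_idx])
            # the top ROC threshold is 1 + eps ("call nothing"); clamp into [0, 1]
            net.cutoff = min(
                optimal_cutoff(roc_curve(train_probs, y[train_idx])), 1.0
            )
            results.append(_evaluate_fold(net, X[val_idx], y[val_idx]))
        except PadRbfError as exc:
            raise PadRbfError(f"fold {fold} failed: {exc}") from exc
    return results


def select_center_count(
    X, y,
    counts=range(2, 51),
    plan: FoldPlan | None = None,
    eta: float = 0.6,
    seed: int | None = None,
    kmeans_mode: str = "batch",
) -> SweepResult:
    """Sweep hidden-node counts; pick the argmin of mean validation MSE.

    MSE is measured on raw network scores against the -1/+1 targets (the
    training objective), averaged over validation folds.  Counts infeasible
    for some training partition are skipped with a warning and recorded as
    NaN; ties at the minimum go to the smallest count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    counts = list(counts)
    if not counts:
        raise ValueError("counts must be non-empty")
    if plan is None:
        plan = stratified_kfold(y, k=10, seed=seed)
    mse_per_count = []
    for count in counts:
        fold_mse = []
        try:
            for fold in range(plan.k):
                train_idx, val_idx = plan.train_val_indices(fold)
                net = rbf.train(
                    X[train_idx], y[train_idx], n_hidden=count, eta=eta,
                    seed=_child_seed(seed, count, fold), kmeans_mode=kmeans_mode,
                )
                scores = rbf.predict_score(net, X[val_idx])
                fold_mse.append(float(np.mean((scores - y[val_idx]) ** 2)))
            mse_per_count.append(float(np.mean(fold_mse)))
        except InfeasibleKError:
            warnings.warn(f"center count {count} infeasible; recorded as missing")
            mse_per_count.append(float("nan"))
    arr = np.asarray(mse_per_count)
    if np.all(np.isnan(arr)):
        raise InfeasibleKError("no feasible center count in the sweep")
    best = int(np.nanargmin(arr))  # first minimum -> smallest count on ties
    return SweepResult(center_counts=counts, mse_per_count=mse_per_count,
                       best_count=counts[best])


def _indicator_vectors(folds: list[IndicatorSet], name: str) -> np.ndarray:
    return np.array([getattr(f, name) for f in folds], dtype=float)


def compare_models(
    folds_a: list[IndicatorSet],
    folds_b: list[IndicatorSet],
    alpha: float = 0.05,
    mode: str = "unpaired",
    bonferroni: bool = False,
) -> list[ComparisonRow]:
    """Two-tailed t-tests on each indicator's per-fold values.

    ``unpaired`` uses the pooled-variance two-sample test (df = 2k - 2);
    ``paired`` pairs folds (df = k - 1).  Identical zero-variance vectors
    give t = 0, p = 1 rather than an error.  ``bonferroni`` divides alpha by
    the number of indicators tested.
    """
    if mode not in ("unpaired", "paired"):
        raise ValueError(f"mode must be 'unpaired' or 'paired', got {mode!r}")
    if len(folds_a) != len(folds_b):
        raise ValueError("fold counts differ between models")
    if len(folds_a) < 2:
        raise ValueError("need at least 2 folds per model")
    threshold = alpha / len(INDICATOR_NAMES) if bonferroni else alpha
    rows = []
    for name in INDICATOR_NAMES:
        a = _indicator_vectors(folds_a, name)
        b = _indicator_vectors(folds_b, name)
        if np.allclose(a, b, equal_nan=True) or (
            np.nanstd(a) == 0 and np.nanstd(b) == 0
            and np.nanmean(a) == np.nanmean(b)
        ):
            t_stat, p_val = 0.0, 1.0
        elif mode == "unpaired":
            t_stat, p_val = stats.ttest_ind(a, b, equal_var=True,
                                            nan_policy="omit")
        else:
            t_stat, p_val = stats.ttest_rel(a, b, nan_policy="omit")
        rows.append(ComparisonRow(
            indicator=name,
            summary_a=summarize_folds(a),
            summary_b=summarize_folds(b),
            t_statistic=float(t_stat),
            p_value=float(p_val),
            significant=bool(p_val < threshold),
        ))
    return rows
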