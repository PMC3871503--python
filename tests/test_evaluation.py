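import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from padrbf import evaluation as ev
from padrbf.errors import UndefinedROCError


# ---------------------------------------------------------------------------
# independent oracles

def mann_whitney_auc(probs, labels):
    """Exhaustive pairwise comparison: P(s+ > s-) + 0.5 P(s+ = s-)."""
    pos = [p for p, l in zip(probs, labels) if l == 1]
    neg = [p for p, l in zip(probs, labels) if l == -1]
    wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


def brute_force_points(probs, labels):
    """Every achievable (fpr, tpr) from exhaustive threshold enumeration."""
    probs = np.asarray(probs)
    labels = np.asarray(labels)
    candidates = sorted(set(probs) | {0.0, 2.0})
    points = set()
    for t in candidates:
        pred = np.where(probs >= t, 1, -1)
        tpr = np.mean(pred[labels == 1] == 1)
        fpr = np.mean(pred[labels == -1] == 1)
        points.add((round(fpr, 12), round(tpr, 12)))
    return points


class TestConfusion:
    def test_basic_counts(self):
        cm = ev.confusion([1, 1, -1], [1, 1, -1])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 1, 0, 0)

    def test_all_positive_predictions(self):
        cm = ev.confusion([1, -1], [1, 1])
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 0, 0)

    def test_swapping_positive_label_transposes(self):
        labels = [1, 1, -1, -1, 1]
        preds = [1, -1, -1, 1, 1]
        a = ev.confusion(labels, preds, positive_label=1)
        b = ev.confusion(labels, preds, positive_label=-1)
        assert (a.tp, a.tn, a.fp, a.fn) == (b.tn, b.tp, b.fn, b.fp)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion([], [])


class TestIndicators:
    def test_published_rate_identities(self):
        # mean rates reported for the RBF model reproduce its Youden/F-score
        assert ev.youden_index(0.953, 0.948) == pytest.approx(0.901, abs=5e-4)
        assert ev.f_score(0.953, 0.942) == pytest.approx(0.947, abs=5e-4)

    def test_perfect_classifier(self):
        out = ev.indicators(ev.ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv",
                     "f_score", "youden"):
            assert getattr(out, name) == pytest.approx(1.0)

    def test_zero_denominator_flags_nan(self):
        out = ev.indicators(ev.ConfusionMatrix(tp=0, fp=0, fn=0, tn=4))
        assert math.isnan(out.sensitivity)   # no positives present
        assert math.isnan(out.ppv)           # no positive calls
        assert out.specificity == 1.0

    @given(tp=st.integers(0, 30), fp=st.integers(0, 30),
           fn=st.integers(0, 30), tn=st.integers(0, 30))
    def test_identities_hold_for_all_matrices(self, tp, fp, fn, tn):
        if tp + fp + fn + tn == 0:
            return
        out = ev.indicators(ev.ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        if not (math.isnan(out.sensitivity) or math.isnan(out.specificity)):
            assert out.youden == pytest.approx(
                out.sensitivity + out.specificity - 1)
        if not math.isnan(out.f_score):
            assert out.f_score == pytest.approx(
                2 * out.sensitivity * out.ppv / (out.sensitivity + out.ppv))


class TestRoc:
    def test_perfect_separation_passes_corner(self):
        roc = ev.roc_curve([0.1, 0.2, 0.8, 0.9], [-1, -1, 1, 1])
        assert (0.0, 1.0) in set(zip(roc.fpr, roc.tpr))
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert ev.auc(roc) == 1.0

    def test_null_scores_give_half_auc(self):
        rng = np.random.default_rng(0)
        probs = rng.uniform(size=4000)
        labels = rng.choice([-1, 1], size=4000)
        assert ev.auc(ev.roc_curve(probs, labels)) == pytest.approx(0.5, abs=0.03)

    def test_matches_exhaustive_threshold_enumeration(self):
        probs = [0.1, 0.4, 0.35, 0.8, 0.8, 0.05]
        labels = [-1, 1, -1, 1, 1, -1]
        roc = ev.roc_curve(probs, labels)
        ours = {(round(f, 12), round(t, 12)) for f, t in zip(roc.fpr, roc.tpr)}
        assert ours == brute_force_points(probs, labels)

    def test_monotone_in_both_coordinates(self):
        rng = np.random.default_rng(1)
        probs = rng.uniform(size=60)
        labels = rng.choice([-1, 1], size=60)
        roc = ev.roc_curve(probs, labels)
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedROCError):
            ev.roc_curve([0.1, 0.9], [1, 1])


class TestAuc:
    @pytest.mark.parametrize("seed,n", [(0, 10), (1, 25), (2, 50)])
    def test_equals_mann_whitney_pair_count(self, seed, n):
        rng = np.random.default_rng(seed)
        probs = np.round(rng.uniform(size=n), 1)   # force ties
        labels = rng.choice([-1, 1], size=n)
        if len(set(labels)) < 2:
            labels[0] = -labels[0]
        assert ev.auc(ev.roc_curve(probs, labels)) == pytest.approx(
            mann_whitney_auc(probs, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(3)
        probs = rng.uniform(size=80)
        labels = rng.choice([-1, 1], size=80)
        assert ev.auc(ev.roc_curve(probs, labels)) == pytest.approx(
            roc_auc_score(labels, probs), abs=1e-12)

    def test_score_negation_complements(self):
        rng = np.random.default_rng(4)
        probs = rng.uniform(0.05, 0.95, size=40)   # tie-free
        labels = rng.choice([-1, 1], size=40)
        a = ev.auc(ev.roc_curve(probs, labels))
        b = ev.auc(ev.roc_curve(1 - probs, labels))
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestOptimalCutoff:
    def test_perfectly_separated_pair(self):
        cut = ev.optimal_cutoff(ev.roc_curve([0.2, 0.8], [-1, 1]))
        assert cut == pytest.approx(0.8)   # smallest candidate in (0.2, 0.8]

    def test_null_scores_have_near_zero_youden(self):
        rng = np.random.default_rng(5)
        probs = rng.uniform(size=3000)
        labels = rng.choice([-1, 1], size=3000)
        roc = ev.roc_curve(probs, labels)
        best = np.max(roc.tpr - roc.fpr)
        assert best < 0.1

    def test_matches_brute_force_search(self):
        probs = [0.15, 0.3, 0.3, 0.55, 0.6, 0.75, 0.8, 0.95]
        labels = [-1, -1, 1, -1, 1, 1, -1, 1]
        roc = ev.roc_curve(probs, labels)
        cut = ev.optimal_cutoff(roc)

        def youden_at(t):
            pred = np.where(np.asarray(probs) >= t, 1, -1)
            sens = np.mean(pred[np.asarray(labels) == 1] == 1)
            spec = np.mean(pred[np.asarray(labels) == -1] == -1)
            return sens + spec - 1

        candidates = sorted(set(probs) | {0.0, 2.0})
        best = max(youden_at(t) for t in candidates)
        assert youden_at(cut) == pytest.approx(best)
        # tie-break: no smaller candidate achieves the same value
        for t in candidates:
            if t < cut:
                assert youden_at(t) < best


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero(self):
        # two blocks whose mean predicted risk equals the observed event rate
        probs = np.array([0.2] * 10 + [0.8] * 10)
        labels = np.array([1] * 2 + [-1] * 8 + [1] * 8 + [-1] * 2)
        assert ev.hosmer_lemeshow(probs, labels, n_groups=2) == \
            pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(6)
        probs = rng.uniform(size=50)
        labels = rng.choice([-1, 1], size=50)
        base = ev.hosmer_lemeshow(probs, labels)
        perm = rng.permutation(50)
        assert ev.hosmer_lemeshow(probs[perm], labels[perm]) == \
            pytest.approx(base, abs=1e-9)

    def test_matches_longhand_oracle_on_fixed_input(self):
        rng = np.random.default_rng(40)
        probs = np.sort(rng.uniform(size=40))
        labels = np.where(rng.uniform(size=40) < probs, 1, -1)
        if len(set(labels)) < 2:
            labels[0] = -labels[0]
        # longhand: 10 groups of 4 consecutive sorted samples
        stat = 0.0
        for g in range(10):
            sl = slice(4 * g, 4 * g + 4)
            e1 = probs[sl].sum()
            o1 = np.sum(labels[sl] == 1)
            e0, o0 = 4 - e1, 4 - o1
            stat += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
        assert ev.hosmer_lemeshow(probs, labels) == pytest.approx(stat, rel=1e-9)

    def test_non_negative(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            probs = rng.uniform(size=30)
            labels = rng.choice([-1, 1], size=30)
            if len(set(labels)) < 2:
                continue
            assert ev.hosmer_lemeshow(probs, labels) >= 0

    def test_single_class_rejected_and_small_n_warns(self):
        with pytest.raises(ValueError):
            ev.hosmer_lemeshow([0.2, 0.4], [1, 1])
        with pytest.warns(UserWarning):
            ev.hosmer_lemeshow([0.1, 0.5, 0.9], [-1, 1, 1], n_groups=10)


class TestSummarizeFolds:
    def test_reproduces_published_interval_arithmetic(self):
        # mean 0.950, SD 0.022, k = 10 -> (0.936, 0.964) at 3 dp
        lo, hi = ev.confidence_interval(0.950, 0.022, 10)
        assert round(lo, 3) == 0.936 and round(hi, 3) == 0.964
        # mean 0.953, SD 0.015, k = 10 -> lower bound 0.944 at 3 dp
        lo, _ = ev.confidence_interval(0.953, 0.015, 10)
        assert round(lo, 3) == 0.944

    def test_summary_of_samples(self):
        values = [0.9, 0.92, 0.95, 0.97]
        s = ev.summarize_folds(values)
        assert s.mean == pytest.approx(np.mean(values))
        assert s.sd == pytest.approx(np.std(values, ddof=1))
        assert s.ci_low <= s.mean <= s.ci_high
        assert s.ci_low == pytest.approx(s.mean - 1.96 * s.sd / 2)  # sqrt(4)

    def test_constant_values_degenerate_interval(self):
        s = ev.summarize_folds([0.8] * 6)
        assert s.sd == pytest.approx(0, abs=1e-12)
        assert s.ci_low == pytest.approx(s.mean, abs=1e-12)
        assert s.ci_high == pytest.approx(s.mean, abs=1e-12)
        assert s.mean == pytest.approx(0.8)

    def test_too_few_values_rejected_and_nan_dropped(self):
        with pytest.raises(ValueError):
            ev.summarize_folds([0.5])
        with pytest.warns(UserWarning):
            s = ev.summarize_folds([0.4, 0.6, math.nan])
        assert s.n_folds == 2
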