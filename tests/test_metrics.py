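"""Diagnostic metrics against arithmetic and rank-statistic oracles."""

import numpy as np
import pytest
from scipy import stats

from slsim.errors import MetricsError
from slsim.metrics import (
    average_precision,
    cohen_kappa,
    confusion_metrics,
    evaluate_scores,
    roc_auc,
    youden_threshold,
)


def counts_to_labels(tp, fn, fp, tn):
    y_true = ["pos"] * (tp + fn) + ["neg"] * (fp + tn)
    y_pred = ["pos"] * tp + ["neg"] * fn + ["pos"] * fp + ["neg"] * tn
    return np.array(y_true), np.array(y_pred)


class TestConfusion:
    def test_binary_arithmetic(self):
        """TP=40 FN=10 FP=5 TN=45: acc .85, sens .8, spec .9, prec 8/9."""
        y_true, y_pred = counts_to_labels(40, 10, 5, 45)
        rep = confusion_metrics(y_true, y_pred, ["pos", "neg"])
        assert rep.accuracy == pytest.approx(0.85)
        pos = rep.per_class.loc["pos"]
        assert pos["sensitivity"] == pytest.approx(0.8)
        assert pos["specificity"] == pytest.approx(0.9)
        assert pos["precision"] == pytest.approx(8 / 9)
        f1 = 2 * (8 / 9) * 0.8 / (8 / 9 + 0.8)
        assert pos["f1"] == pytest.approx(f1)

    def test_perfect_prediction(self):
        y = np.array(["a", "b", "c"] * 5)
        rep = confusion_metrics(y, y, ["a", "b", "c"])
        assert rep.accuracy == 1.0
        assert (rep.per_class[["sensitivity", "precision", "f1"]] == 1.0).all().all()

    def test_all_one_class_prediction(self):
        y_true = np.array(["pos", "neg"] * 10)
        y_pred = np.array(["pos"] * 20)
        rep = confusion_metrics(y_true, y_pred, ["pos", "neg"])
        assert rep.per_class.loc["pos", "specificity"] == 0.0

    def test_absent_class_reported_missing(self):
        y_true = np.array(["a", "a", "b"])
        y_pred = np.array(["a", "b", "b"])
        rep = confusion_metrics(y_true, y_pred, ["a", "b", "c"])
        assert np.isnan(rep.per_class.loc["c", "sensitivity"])

    def test_errors(self):
        with pytest.raises(MetricsError):
            confusion_metrics([], [], ["a"])
        with pytest.raises(MetricsError):
            confusion_metrics(["a"], ["a", "b"], ["a", "b"])

    def test_permutation_invariance(self, rng):
        y_true = rng.choice(["a", "b", "c"], 60)
        y_pred = rng.choice(["a", "b", "c"], 60)
        perm = rng.permutation(60)
        r1 = confusion_metrics(y_true, y_pred, ["a", "b", "c"])
        r2 = confusion_metrics(y_true[perm], y_pred[perm], ["a", "b", "c"])
        assert r1.accuracy == r2.accuracy
        assert r1.per_class.equals(r2.per_class)

    def test_macro_f1_bounded_by_per_class(self, rng):
        y_true = rng.choice(["a", "b", "c"], 100)
        y_pred = rng.choice(["a", "b", "c"], 100)
        rep = confusion_metrics(y_true, y_pred, ["a", "b", "c"])
        f1s = rep.per_class["f1"].dropna()
        assert f1s.min() - 1e-12 <= rep.macro["f1_macro"] <= f1s.max() + 1e-12


def rank_statistic_auc(scores, labels):
    """Independent oracle: P(random positive outscores random negative),
    ties counted one half — explicit pairwise comparison."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        *_, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_all_tied_scores(self):
        scores = np.full(10, 0.5)
        labels = np.array([1, 0] * 5)
        *_, auc = roc_auc(scores, labels)
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(MetricsError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_trapezoid_equals_rank_statistic(self, rng):
        """Trapezoid area == Mann-Whitney statistic, with ties injected."""
        for trial in range(25):
            n = int(rng.integers(10, 60))
            scores = np.round(rng.random(n), 2)  # rounding injects ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            *_, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(rank_statistic_auc(scores, labels), abs=1e-12)

    def test_rank_oracle_matches_scipy(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        n1, n0 = (labels == 1).sum(), (labels == 0).sum()
        assert rank_statistic_auc(scores, labels) == pytest.approx(u / (n1 * n0))


def brute_force_youden(scores, labels):
    """Sweep every observed score as threshold (score >= t -> positive)."""
    best_t, best_j = None, -np.inf
    for t in sorted(set(scores)):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if j > best_j or (j == best_j and t < best_t):
            best_t, best_j = t, j
    return best_t, best_j


class TestYouden:
    def test_toy_example_against_sweep_oracle(self):
        scores = np.array([0.9, 0.8, 0.6, 0.4, 0.3, 0.55])
        labels = np.array([1, 1, 1, 0, 0, 0])
        fpr, tpr, thr, _ = roc_auc(scores, labels)
        t, j = youden_threshold(fpr, tpr, thr)
        oracle_t, oracle_j = brute_force_youden(scores, labels)
        assert (t, j) == (oracle_t, oracle_j) == (0.6, 1.0)

    def test_perfect_separation_lowest_threshold(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        fpr, tpr, thr, _ = roc_auc(scores, labels)
        t, j = youden_threshold(fpr, tpr, thr)
        assert j == 1.0
        assert t == 0.8  # lowest threshold attaining J=1 among candidates

    def test_uninformative_scores(self):
        scores = np.full(6, 0.5)
        labels = np.array([1, 0] * 3)
        fpr, tpr, thr, _ = roc_auc(scores, labels)
        _, j = youden_threshold(fpr, tpr, thr)
        assert j == 0.0

    def test_matches_sweep_on_random_data(self, rng):
        for _ in range(20):
            scores = np.round(rng.random(40), 2)
            labels = rng.integers(0, 2, 40)
            if labels.min() == labels.max():
                continue
            fpr, tpr, thr, _ = roc_auc(scores, labels)
            t, j = youden_threshold(fpr, tpr, thr)
            _, oracle_j = brute_force_youden(scores, labels)
            assert j == pytest.approx(oracle_j, abs=1e-12)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0, 0])
        *_, ap = average_precision(scores, labels)
        assert ap == 1.0

    def test_reversed_ranking_single_positive(self):
        """One positive ranked last of four: single PR step at recall 1
        with precision 1/4."""
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        labels = np.array([0, 0, 0, 1])
        *_, ap = average_precision(scores, labels)
        assert ap == pytest.approx(0.25)

    def test_no_positive_rejected(self):
        with pytest.raises(MetricsError):
            average_precision(np.array([0.5, 0.6]), np.array([0, 0]))

    def test_bounded(self, rng):
        for _ in range(10):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            if labels.sum() == 0:
                continue
            *_, ap = average_precision(scores, labels)
            assert 0.0 <= ap <= 1.0


class TestKappa:
    def test_identical_ratings(self):
        a = np.array(["x", "y", "z"] * 10)
        assert cohen_kappa(a, a) == 1.0

    def test_marginal_arithmetic(self):
        """Agreement table [[40,10],[5,45]]: p_o=.85, p_e=.5, kappa=.7."""
        a, b = counts_to_labels(40, 10, 5, 45)
        assert cohen_kappa(a, b) == pytest.approx(0.7)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(cohen_kappa(a, b)) < 0.05

    def test_degenerate_marginals_nan(self):
        a = np.array(["x", "x", "x"])
        assert np.isnan(cohen_kappa(a, a))

    def test_length_mismatch(self):
        with pytest.raises(MetricsError):
            cohen_kappa([1, 2], [1])


class TestEvaluateScores:
    def test_full_report_on_separable_scores(self, rng):
        labels = ["a", "b", "c"]
        y = np.array(labels * 20)
        proba = np.zeros((60, 3))
        for i, lab in enumerate(y):
            proba[i] = 0.1
            proba[i, labels.index(lab)] = 0.8
        rep = evaluate_scores(y, proba, labels)
        assert rep.accuracy == 1.0
        assert rep.macro["auroc_macro"] == 1.0
        assert rep.macro["map_macro"] == 1.0

    def test_metric_ranges(self, rng):
        labels = ["a", "b", "c"]
        y = rng.choice(labels, 90)
        proba = rng.dirichlet(np.ones(3), 90)
        rep = evaluate_scores(y, proba, labels)
        vals = rep.per_class.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()
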