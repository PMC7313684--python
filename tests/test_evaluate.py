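"""Repeated-trial protocol and statistics: Welch t against the textbook
formula, Holm step-down behaviour, confusion normalization, summaries."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import special as sp_special

import myogest as mg
from myogest.evaluate import _normalize_counts


def welch_formula(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Direct textbook Welch statistic + Welch-Satterthwaite df oracle."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * (1 - sp_special.stdtr(df, abs(t)))
    return t, p


class TestRunTrials:
    def test_thirty_trials_yield_thirty_accuracies(self, small_features):
        X, y = small_features
        res = mg.run_trials(mg.ClassifierSpec(kind="dt"), X, y, n_trials=30, seed=1)
        assert res.train_accuracies.shape == (30,)
        assert res.test_accuracies.shape == (30,)
        assert np.all((res.test_accuracies >= 0) & (res.test_accuracies <= 100))

    def test_single_trial(self, small_features):
        X, y = small_features
        res = mg.run_trials(mg.ClassifierSpec(kind="dt"), X, y, n_trials=1, seed=2)
        assert res.n_trials == 1

    def test_same_master_seed_identical(self, small_features):
        X, y = small_features
        a = mg.run_trials(mg.ClassifierSpec(kind="svm"), X, y, n_trials=4, seed=9)
        b = mg.run_trials(mg.ClassifierSpec(kind="svm"), X, y, n_trials=4, seed=9)
        np.testing.assert_array_equal(a.test_accuracies, b.test_accuracies)
        np.testing.assert_array_equal(a.confusion_counts, b.confusion_counts)


class TestConfusion:
    @pytest.fixture(scope="class")
    def fitted(self, small_features):
        X, y = small_features
        model = mg.train(mg.ClassifierSpec(kind="svm", seed=0), X, y)
        return model, X, y

    def test_perfect_predictions_give_identity(self, separable_toy):
        X, y = separable_toy
        model = mg.train(mg.ClassifierSpec(kind="dt"), X, y)
        cm = mg.confusion(model, X, y)
        np.testing.assert_allclose(cm.rows_percent, 100 * np.eye(4), atol=1e-9)
        assert cm.overall_accuracy == 100.0

    def test_rows_sum_to_100(self, fitted):
        model, X, y = fitted
        cm = mg.confusion(model, X, y)
        np.testing.assert_allclose(cm.rows_percent.sum(axis=1), 100.0, atol=0.01)
        assert np.all(cm.rows_percent >= 0)

    def test_known_counts_arithmetic(self):
        counts = np.eye(4, dtype=int) * 10
        counts[0, 0], counts[0, 1] = 9, 1  # 10 true close: 9 -> close, 1 -> open
        cm = _normalize_counts(counts)
        np.testing.assert_allclose(cm.rows_percent[0], [90.0, 10.0, 0.0, 0.0])

    def test_missing_class_rejected(self, fitted):
        model, X, y = fitted
        mask = y != 3
        with pytest.raises(ValueError):
            mg.confusion(model, X[mask], y[mask])


class TestWelch:
    def test_identical_samples_null(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = mg.welch_t(a, a)
        assert t == 0.0 and p == 1.0

    def test_extreme_separation(self):
        rng = np.random.default_rng(0)
        a = 0.0 + 1e-6 * rng.standard_normal(4)
        b = 10.0 + 1e-6 * rng.standard_normal(4)
        _, p = mg.welch_t(a, b)
        assert p < 0.01

    def test_matches_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        t, p = mg.welch_t(a, b)
        t_ref, p_ref = welch_formula(a, b)
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_degenerate_equal_constants(self):
        t, p = mg.welch_t(np.full(5, 2.0), np.full(3, 2.0))
        assert (t, p) == (0.0, 1.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mg.welch_t(np.array([1.0]), np.array([1.0, 2.0]))


class TestHolm:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(mg.holm_adjust(np.array([0.04])), [0.04])

    def test_hand_executed_step_down(self):
        np.testing.assert_allclose(
            mg.holm_adjust(np.array([0.01, 0.04, 0.03])), [0.03, 0.06, 0.06]
        )

    def test_dominates_raw_and_capped(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 8))
            adj = mg.holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)

    def test_bonferroni_significance_implies_holm(self):
        """Holm is uniformly more powerful than Bonferroni: anything
        Bonferroni rejects at alpha, Holm rejects too (1000 random vectors)."""
        rng = np.random.default_rng(11)
        alpha = 0.05
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(2, 8)) ** 3  # skew towards small p
            holm = mg.holm_adjust(p)
            bonf = np.minimum(p * p.size, 1.0)
            assert np.all(holm[bonf < alpha] < alpha)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            mg.holm_adjust(np.array([0.5, 1.2]))


def _result(kind: str, test_acc: np.ndarray) -> mg.TrialResultSet:
    return mg.TrialResultSet(
        kind=kind, train_accuracies=test_acc, test_accuracies=test_acc
    )


class TestCompare:
    def test_three_classifiers_three_pairs(self):
        rng = np.random.default_rng(3)
        results = [
            _result(k, np.clip(m + rng.standard_normal(10), 0, 100))
            for k, m in [("svm", 90.0), ("ann", 84.0), ("dt", 70.0)]
        ]
        report = mg.compare(results)
        assert len(report.pairwise) == 3
        assert report.best_classifier == "svm"
        for pw in report.pairwise:
            assert pw.p_holm >= pw.p_raw - 1e-15
            assert pw.p_holm <= 1.0

    def test_identical_result_sets_not_significant(self):
        acc = np.array([80.0, 82.0, 78.0, 81.0, 79.0])
        report = mg.compare([_result(k, acc) for k in ("svm", "ann", "dt")])
        assert all(pw.p_holm == 1.0 for pw in report.pairwise)

    def test_summary_statistics_against_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        accs = {k: np.clip(80 + 5 * rng.standard_normal(12), 0, 100) for k in ("svm", "dt")}
        report = mg.compare([_result(k, a) for k, a in accs.items()])
        for k, a in accs.items():
            mean = a.sum() / a.size
            sd = np.sqrt(((a - mean) ** 2).sum() / (a.size - 1))
            assert report.summary.loc[k, "test_mean"] == pytest.approx(mean, abs=1e-12)
            assert report.summary.loc[k, "test_sd"] == pytest.approx(sd, abs=1e-12)
            assert a.min() <= report.summary.loc[k, "test_mean"] <= a.max()

    def test_mismatched_trial_counts_rejected(self):
        with pytest.raises(ValueError):
            mg.compare([_result("svm", np.zeros(5)), _result("dt", np.zeros(6))])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            mg.compare([_result("svm", np.zeros(5))])
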