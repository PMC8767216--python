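"""Logistic criticality models, metrics, CV and model comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import matthews_corrcoef

from boolcrit.models import (
    fit_interaction_model,
    fit_model,
    nested_cv,
    paired_one_sided_t_test,
    pareto_select,
    records_frame,
    score,
    st_theoretical_classify,
)


def synthetic_records(n, c_true, steepness, seed):
    """Records labelled by the boundary c * <k_e> p(1-p) = 1 with
    logistic label noise of the given steepness."""
    rng = np.random.default_rng(seed)
    ke = rng.uniform(1.0, 8.0, size=n)
    p = rng.uniform(0.05, 0.5, size=n)
    z = steepness * (c_true * ke * p * (1 - p) - 1.0)
    labels = rng.random(n) < 1.0 / (1.0 + np.exp(-z))
    return pd.DataFrame({
        "k": np.full(n, 8.0), "p": p, "mean_ke": ke,
        "zeta": labels.astype(float) + 0.5, "chaotic": labels.astype(int)})


class TestScore:
    def test_printed_formula_example(self):
        preds = [1] * 45 + [0] * 5 + [0] * 45 + [1] * 5
        labels = [1] * 50 + [0] * 50
        assert score(preds, labels).mcc == pytest.approx(0.8)

    def test_perfect_predictions(self):
        labels = [0, 1, 1, 0, 1]
        rep = score(labels, labels, scores=labels)
        assert rep.mcc == 1.0 and rep.auc == 1.0

    def test_zero_denominator_gives_zero(self):
        assert score([1, 1, 1], [1, 1, 0]).mcc == 0.0

    def test_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 2, 50)
            yhat = rng.integers(0, 2, 50)
            assert score(yhat, y).mcc == pytest.approx(
                matthews_corrcoef(y, yhat), abs=1e-12)

    def test_auc_equals_normalized_mann_whitney(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 80)
        s = rng.random(80)
        u = sps.mannwhitneyu(s[y == 1], s[y == 0],
                             alternative="two-sided").statistic
        expected = u / ((y == 1).sum() * (y == 0).sum())
        assert score(y, y, scores=s).auc == pytest.approx(expected)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        assert score(y, y, scores=s).auc == pytest.approx(0.5, abs=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            score([], [])


class TestStructuralTheory:
    def test_boundary_cases(self):
        assert st_theoretical_classify(2, 0.5) == 0  # exactly critical
        assert st_theoretical_classify(8, 0.5) == 1
        assert st_theoretical_classify(2, 0.05) == 0


class TestFitModel:
    def test_parameter_recovery_within_5_percent(self):
        df = synthetic_records(1000, c_true=3.9, steepness=8.0, seed=42)
        fitted = fit_model(df, class_id=2, kappa="ke")
        c_hat = fitted.boundary["kappa*pq"]
        assert abs(c_hat - 3.9) / 3.9 < 0.05

    def test_boundary_points_have_half_probability(self):
        df = synthetic_records(500, c_true=3.0, steepness=6.0, seed=3)
        fitted = fit_model(df, class_id=2, kappa="ke")
        c = fitted.boundary["kappa*pq"]
        # construct points exactly on the boundary: ke * pq = 1 / c
        probe = pd.DataFrame({
            "k": [8.0] * 5, "p": np.linspace(0.1, 0.5, 5)})
        probe["mean_ke"] = 1.0 / (c * probe.p * (1 - probe.p))
        probs = fitted.predict_proba(probe)
        assert np.allclose(probs, 0.5, atol=1e-9)

    def test_single_label_rejected(self):
        df = synthetic_records(100, 3.0, 6.0, 4)
        df["chaotic"] = 1
        with pytest.raises(ValueError):
            fit_model(df, 2, "ke")

    def test_invalid_arguments(self):
        df = synthetic_records(100, 3.0, 6.0, 5)
        with pytest.raises(ValueError):
            fit_model(df, 7, "ke")
        with pytest.raises(ValueError):
            fit_model(df, 2, "sensitivity")

    def test_interaction_model_ignores_irrelevant_terms(self):
        """When the label depends only on <k_e>, the k and interaction
        coefficients vanish relative to the <k_e> coefficient."""
        rng = np.random.default_rng(6)
        n = 4000
        ke = rng.uniform(1, 6, n)
        k = rng.choice([2.0, 4.0, 8.0], n)
        z = 6.0 * (ke - 2.0)
        labels = rng.random(n) < 1 / (1 + np.exp(-z))
        df = pd.DataFrame({"k": k, "p": np.full(n, 0.3), "mean_ke": ke,
                           "zeta": labels + 0.5,
                           "chaotic": labels.astype(int)})
        fitted = fit_interaction_model(df)
        beta_ke = fitted.coefficients["mean_ke"]
        assert abs(fitted.coefficients["k"]) < 0.2 * abs(beta_ke)
        assert abs(fitted.coefficients["kappa_k*kappa_ke"]) < 0.2 * abs(beta_ke)


class TestNestedCV:
    def test_sixteen_folds_and_determinism(self):
        df = synthetic_records(400, 3.5, 6.0, 7)
        reps = nested_cv(df, 2, "ke", master_seed=11)
        again = nested_cv(df, 2, "ke", master_seed=11)
        assert len(reps) == 16
        assert [r.mcc for r in reps] == [r.mcc for r in again]
        assert all(np.isfinite(r.r2) for r in reps)

    def test_insufficient_data_rejected(self):
        df = synthetic_records(20, 3.5, 6.0, 8)
        df.loc[:17, "chaotic"] = 1
        with pytest.raises(ValueError):
            nested_cv(df, 2, "ke")

    def test_true_model_class_beats_lower_class(self):
        """Data generated from a class-2 rule: class-2 CV MCC is at
        least that of class 1."""
        df = synthetic_records(1500, 3.9, 10.0, 9)
        mcc2 = np.mean([r.mcc for r in nested_cv(df, 2, "ke", 1)])
        mcc1 = np.mean([r.mcc for r in nested_cv(df, 1, "ke", 1)])
        assert mcc2 >= mcc1 - 0.02


class TestPairedTTest:
    def test_identical_vectors(self):
        res = paired_one_sided_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.p_value == 0.5 and res.degenerate

    def test_constant_uplift_degenerate(self):
        res = paired_one_sided_t_test([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        assert res.p_value == 0.0 and res.degenerate

    def test_matches_scipy_one_sided(self):
        rng = np.random.default_rng(10)
        a, b = rng.random(16), rng.random(16)
        res = paired_one_sided_t_test(a, b)
        ref = sps.ttest_rel(b, a, alternative="greater")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)

    def test_p_value_uniform_under_null(self):
        rng = np.random.default_rng(12)
        pvals = []
        for _ in range(1000):
            a = rng.normal(size=8)
            b = rng.normal(size=8)
            pvals.append(paired_one_sided_t_test(a, b).p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestParetoSelect:
    def test_substantial_rise_then_plateau(self):
        assert pareto_select([0.0, 0.96, 0.96, 0.97, 0.97, 0.97],
                             delta=0.01) == 2

    def test_strictly_increasing_large_steps(self):
        assert pareto_select([0.1, 0.3, 0.5, 0.7, 0.9, 1.0], delta=0.01) == 6

    def test_all_equal_prefers_simplest(self):
        assert pareto_select([0.5] * 6) == 1


def test_records_frame_adds_compound_bias_term():
    df = synthetic_records(10, 3.0, 5.0, 13)
    out = records_frame(df)
    assert np.allclose(out["pq"], out["p"] * (1 - out["p"]))
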