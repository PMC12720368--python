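"""Covariate adjustment, t-maps, demographic statistics, FDR."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mindsubtypes.casecontrol import (
    adjust_covariates,
    bh_fdr,
    chi_square_2x2,
    clinical_corr_map,
    demographics_report,
    group_ttest,
    mann_whitney,
    quadratic_trajectory,
    two_sample_t_summary,
)


def _covariates(n, rng):
    return pd.DataFrame({
        "sex": rng.integers(0, 2, n),
        "age": rng.normal(58, 7, n),
        "tiv": rng.normal(1.5e6, 1e5, n),
    })


class TestAdjustCovariates:
    def test_perfect_regression_constant_residual(self):
        rng = np.random.default_rng(0)
        cov = _covariates(50, rng)
        values = 2.0 * cov["age"].to_numpy()[:, None] * np.ones((1, 3))
        adjusted, _ = adjust_covariates(values, cov)
        assert np.ptp(adjusted, axis=0).max() < 1e-8

    def test_residual_orthogonality(self):
        rng = np.random.default_rng(1)
        cov = _covariates(60, rng)
        values = rng.normal(size=(60, 10)) + 0.01 * cov["age"].to_numpy()[:, None]
        _, model = adjust_covariates(values, cov)
        for c in ("sex", "age", "tiv"):
            x = cov[c].to_numpy(dtype=float)
            corr = np.abs([np.corrcoef(model.residuals[:, j], x)[0, 1]
                           for j in range(10)])
            assert corr.max() < 1e-8

    def test_zero_effect_covariates_leave_values_alone(self):
        # with zero true betas the only change is the OLS projection onto the
        # 3 covariate columns: E|change| = sqrt(2/pi) * sd * sqrt(3/n) ~ 0.098
        rng = np.random.default_rng(2)
        cov = _covariates(200, rng)
        values = rng.normal(0, 1, size=(200, 5))
        adjusted, model = adjust_covariates(values, cov)
        change = np.abs(adjusted - values).mean()
        expected = np.sqrt(2 / np.pi) * np.sqrt(3 / 200)
        assert 0.5 * expected < change < 1.5 * expected
        np.testing.assert_allclose(model.intercept, values.mean(axis=0), atol=1e-10)

    def test_constant_sex_named(self):
        rng = np.random.default_rng(3)
        cov = _covariates(20, rng)
        cov["sex"] = 1
        with pytest.raises(ValueError, match="sex"):
            adjust_covariates(rng.normal(size=(20, 2)), cov)


class TestGroupTtest:
    def test_contrast_antisymmetry(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 8))
        g = np.r_[-np.ones(15), np.ones(15)]
        a = group_ttest(x, g)
        b = group_ttest(x, -g)
        np.testing.assert_allclose(a.t, -b.t, atol=1e-12)
        np.testing.assert_array_equal(a.p, b.p)

    def test_null_familywise_calibration(self):
        """Bonferroni familywise error over 40 regions stays near nominal."""
        flagged = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(30, 40))
            g = np.r_[-np.ones(15), np.ones(15)]
            flagged += group_ttest(x, g).corrected_significant.any()
        assert flagged / 200 <= 0.08

    def test_planted_power_and_direction(self, planted_cohort, planted_strengths):
        b = planted_cohort
        adjusted, _ = adjust_covariates(planted_strengths, b.covariates)
        grp = np.where(b.true_subtype == 0, -1, 0)
        grp[b.true_subtype == 1] = 1
        tm = group_ttest(adjusted, grp)
        planted = b.planted_regions[1] - 1
        assert tm.t[planted].mean() < 0
        assert tm.corrected_significant.sum() >= 1

    def test_sign_matches_mean_difference(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(24, 6))
        g = np.r_[-np.ones(12), np.ones(12)]
        tm = group_ttest(x, g)
        diff = x[g == 1].mean(axis=0) - x[g == -1].mean(axis=0)
        np.testing.assert_array_equal(np.sign(tm.t), np.sign(diff))


class TestChiSquare:
    def test_table1_subtype1_vs_hc(self):
        stat, p = chi_square_2x2([[44, 57], [27, 40]])
        assert stat == pytest.approx(0.176, abs=5e-4)
        assert p == pytest.approx(0.675, abs=5e-4)

    def test_table1_subtype2_vs_hc(self):
        stat, p = chi_square_2x2([[44, 57], [29, 31]])
        assert stat == pytest.approx(0.345, abs=5e-4)
        assert p == pytest.approx(0.557, abs=5e-4)

    def test_table1_subtype1_vs_subtype2(self):
        _, p = chi_square_2x2([[27, 40], [29, 31]])
        assert p == pytest.approx(0.363, abs=5e-4)

    def test_independence_gives_zero(self):
        stat, p = chi_square_2x2([[10, 10], [10, 10]])
        assert stat == 0.0 and p == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestTSummary:
    def test_equal_means_zero(self):
        t, df, p = two_sample_t_summary(5, 1, 10, 5, 2, 12)
        assert t == 0.0 and p == 1.0

    def test_worked_value(self):
        # pooled SE = 2*sqrt(2/16) = 0.7071 => t = 2/0.7071
        t, df, _ = two_sample_t_summary(10, 2, 16, 8, 2, 16)
        assert t == pytest.approx(2.828, abs=5e-4)
        assert df == 30

    def test_table1_age_comparison(self):
        t, df, p = two_sample_t_summary(58.03, 6.03, 101, 57.91, 8.77, 67)
        assert t == pytest.approx(0.104, abs=0.01)
        assert p == pytest.approx(0.917, abs=0.01)

    def test_zero_variance_flagged_infinite(self):
        t, _, p = two_sample_t_summary(3, 0, 5, 1, 0, 5)
        assert np.isinf(t) and t > 0 and p == 0.0


class TestMannWhitney:
    def test_complete_separation(self):
        u, z, _ = mann_whitney([4, 5, 6], [1, 2, 3])
        assert u == 9  # n_x * n_y

    def test_identical_multisets(self):
        u, z, _ = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == 4.5  # n_x * n_y / 2
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_exact_small_sample_p(self):
        # all C(6,3)=20 rank splits; 2 are as extreme => p = 0.1
        u, _, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestClinicalCorr:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 5))
        tab = clinical_corr_map(x, x[:, 2])
        assert tab["r"][2] == pytest.approx(1.0, abs=1e-12)

    def test_sign_flip_negates_map(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(25, 6))
        s = rng.normal(size=25)
        a = clinical_corr_map(x, s)
        b = clinical_corr_map(x, -s)
        np.testing.assert_allclose(a["r"], -b["r"], atol=1e-12)

    def test_null_rarely_fdr_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            tab = clinical_corr_map(rng.normal(size=(30, 40)), rng.normal(size=30))
            hits += tab["significant"].any()
        assert hits <= 2

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            clinical_corr_map(np.random.default_rng(0).normal(size=(10, 3)),
                              np.ones(10))


class TestQuadraticTrajectory:
    def test_exact_recovery(self):
        age = np.linspace(40, 80, 30)
        y = 3.0 - 0.01 * age ** 2
        fit = quadratic_trajectory(y, age)
        np.testing.assert_allclose(fit.coef, [3.0, 0.0, -0.01], atol=1e-8)

    def test_linear_truth_quadratic_term_null(self):
        insignificant = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            age = rng.uniform(40, 80, 60)
            y = 0.5 - 0.002 * age + rng.normal(0, 0.05, 60)
            insignificant += quadratic_trajectory(y, age).pvalues[2] > 0.05
        assert insignificant >= 18

    def test_three_distinct_ages_rejected(self):
        age = np.array([40, 50, 60, 40, 50, 60], dtype=float)
        with pytest.raises(ValueError, match="distinct"):
            quadratic_trajectory(np.arange(6.0), age)


def bh_oracle(p):
    """Definition-based step-up: p_adj(i) = min_{j >= i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


class TestBhFdr:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_and_constant(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2, atol=1e-12)

    def test_matches_definition_on_permutations(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(size=6)
        for perm in itertools.permutations(range(6)):
            p = base[list(perm)]
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def test_demographics_report_keys(planted_cohort):
    rep = demographics_report(planted_cohort.covariates, planted_cohort.true_subtype)
    assert set(rep) == {"0v1", "0v2", "1v2"}
    assert "sex" in rep["0v1"] and "age" in rep["0v1"]
    assert "updrs_iii" in rep["1v2"]
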