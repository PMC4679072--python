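"""Two-way fit, one-way tests, corrected null F law, multiple testing."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import batchaudit as ba
from batchaudit.design import DesignError

from conftest import null_matrix, random_design


def _matrix(design, values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ba.ExpressionMatrix(
        values, tuple(f"g{k}" for k in range(values.shape[0])), design.sample_ids
    )


class TestFitTwoWay:
    def test_noiseless_recovery(self):
        d = ba.design_from_counts([[2, 3], [3, 2]], groups=("A", "B"))
        beta = np.array([1.0, -2.0])
        gamma = np.array([0.5, -0.5])
        vals = 3.0 + beta[d.group_index] + gamma[d.batch_index]
        fit = ba.fit_two_way(_matrix(d, vals), d)
        assert fit.contrast("A", "B")[0] == pytest.approx(3.0, abs=1e-10)
        assert fit.gamma[0, 0] - fit.gamma[0, 1] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(fit.sigma2, 0.0, atol=1e-18)

    def test_hand_computed_pooled_difference(self):
        """batch1 A={1,2} B={0}; batch2 A={3} B={1,1}: per-batch diffs 1.5 and 2
        with equal weights 2/3 pool to 1.75, equal to the two-way contrast."""
        d = ba.design_from_counts([[2, 1], [1, 2]], groups=("A", "B"))
        vals = np.array([1.0, 2.0, 0.0, 3.0, 1.0, 1.0])
        Y = _matrix(d, vals)
        gd = ba.group_diff_estimate(Y, d, "A", "B")
        np.testing.assert_allclose(gd.delta_per_batch[0], [1.5, 2.0], atol=1e-12)
        np.testing.assert_allclose(gd.nu_per_batch, [2 / 3, 2 / 3], atol=1e-12)
        assert gd.delta[0] == pytest.approx(1.75, abs=1e-12)
        fit = ba.fit_two_way(Y, d)
        assert fit.contrast("A", "B")[0] == pytest.approx(1.75, abs=1e-10)

    def test_reconstruction_and_orthogonality(self):
        rng = np.random.default_rng(20)
        d = random_design(rng, connected=True)
        Y = null_matrix(d, 6, rng)
        fit = ba.fit_two_way(Y, d)
        from batchaudit.adjust import _reordered_values

        values, _ = _reordered_values(Y, d)
        np.testing.assert_allclose(fit.fitted + fit.resid, values, atol=1e-10)
        for i in range(d.m):
            np.testing.assert_allclose(
                fit.resid[:, d.batch_index == i].sum(axis=1), 0.0, atol=1e-8
            )
        for j in range(d.M):
            np.testing.assert_allclose(
                fit.resid[:, d.group_index == j].sum(axis=1), 0.0, atol=1e-8
            )

    def test_contrast_se_is_sigma_over_sqrt_nu(self):
        rng = np.random.default_rng(21)
        tested = 0
        while tested < 20:
            d = random_design(rng, M_max=2, connected=True)
            if d.M != 2:
                continue
            a, b = d.groups[0], d.groups[1]
            ess = ba.effective_sample_size(d, a, b)
            if ess.nu == 0:
                continue
            Y = null_matrix(d, 3, rng)
            fit = ba.fit_two_way(Y, d)
            np.testing.assert_allclose(
                fit.contrast_se(a, b),
                np.sqrt(fit.sigma2 / ess.nu),
                rtol=1e-8,
            )
            tested += 1

    def test_pooled_estimator_equals_least_squares_on_random_designs(self):
        """The precision-weighted within-batch pool and the direct two-way
        least-squares contrast are the same estimator (two-group designs)."""
        rng = np.random.default_rng(22)
        tested = 0
        while tested < 50:
            d = random_design(rng, M_max=2, connected=True)
            if d.M != 2:
                continue
            Y = null_matrix(d, 4, rng)
            fit = ba.fit_two_way(Y, d)
            for a, b in [(d.groups[0], d.groups[1])]:
                gd = ba.group_diff_estimate(Y, d, a, b)
                np.testing.assert_allclose(gd.delta, fit.contrast(a, b), atol=1e-10)
            tested += 1

    def test_matches_statsmodels_ols(self):
        """Independent oracle: OLS with batch and group factors."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(23)
        d = ba.design_from_counts([[1, 5, 2], [5, 1, 3]], groups=("A", "B", "C"))
        Y = null_matrix(d, 1, rng)
        fit = ba.fit_two_way(Y, d)
        df = ba.annotation_frame(d)
        df["y"] = Y.values[0]
        ols = smf.ols("y ~ C(batch) + C(group)", data=df).fit()
        contrast = ols.params["C(group)[T.B]"]
        assert fit.contrast("B", "A")[0] == pytest.approx(contrast, abs=1e-10)
        assert fit.sigma2[0] == pytest.approx(ols.mse_resid, rel=1e-10)
        assert fit.df_resid == int(ols.df_resid)
        se = ols.bse["C(group)[T.B]"]
        assert fit.contrast_se("B", "A")[0] == pytest.approx(se, rel=1e-10)


class TestGroupMeansWithCI:
    def test_single_group_single_batch_is_t_interval(self):
        d = ba.design_from_counts([[5]])
        vals = np.array([1.0, 2.0, 3.0, 4.0, 10.0])
        fit = ba.fit_two_way(_matrix(d, vals), d)
        ci = ba.group_means_with_ci(fit, level=0.95)
        mean, s = vals.mean(), vals.std(ddof=1)
        half = st.t.ppf(0.975, 4) * s / np.sqrt(5)
        assert ci.iloc[0]["estimate"] == pytest.approx(mean, abs=1e-10)
        assert ci.iloc[0]["lower"] == pytest.approx(mean - half, abs=1e-10)
        assert ci.iloc[0]["upper"] == pytest.approx(mean + half, abs=1e-10)

    def test_invalid_level_rejected(self):
        d = ba.design_from_counts([[3, 3]])
        fit = ba.fit_two_way(null_matrix(d, 1, np.random.default_rng(0)), d)
        with pytest.raises(ValueError):
            ba.group_means_with_ci(fit, level=1.5)

    def test_blocked_intervals_wider_than_naive_on_adjusted(self):
        """The two-way intervals carry the batch-estimation uncertainty that
        naive per-group intervals on adjusted data ignore."""
        sc = ba.three_group_scenario(seed=5)
        d = sc["design"]
        fit = ba.fit_two_way(sc["observed"], d)
        ci = ba.group_means_with_ci(fit, level=0.95)
        Yadj = ba.anova_adjust(sc["observed"], d)
        vals = Yadj.values[0]
        ssw = sum(
            ((vals[d.group_index == j] - vals[d.group_index == j].mean()) ** 2).sum()
            for j in range(d.M)
        )
        s_pooled = np.sqrt(ssw / (d.n - d.M))
        tq = st.t.ppf(0.975, d.n - d.M)
        # groups 1 and 2 are the unevenly split ones
        for g in ("group1", "group2"):
            j = d.groups.index(g)
            sel = d.group_index == j
            naive_half = tq * s_pooled / np.sqrt(sel.sum())
            row = ci[ci["group"] == g].iloc[0]
            blocked_half = (row["upper"] - row["lower"]) / 2
            assert blocked_half > naive_half


class TestOnewayF:
    def test_zero_between_group_variation_gives_zero_F(self):
        d = ba.design_from_counts([[2, 2]], groups=("A", "B"))
        vals = np.array([1.0, -1.0, 1.0, -1.0])  # equal group means
        res = ba.oneway_f_test(_matrix(d, vals), d)
        assert res["F"][0] == pytest.approx(0.0, abs=1e-12)

    def test_two_group_F_equals_squared_t(self):
        rng = np.random.default_rng(24)
        d = ba.design_from_counts([[3, 4], [2, 3]], groups=("A", "B"))
        Y = null_matrix(d, 10, rng)
        res = ba.oneway_f_test(Y, d)
        ja = d.group_index == 0
        t = np.array(
            [
                st.ttest_ind(Y.values[k, ja], Y.values[k, ~ja], equal_var=True).statistic
                for k in range(10)
            ]
        )
        np.testing.assert_allclose(res["F"], t**2, atol=1e-10)

    def test_mean_F_matches_corrected_law_prediction(self):
        """On adjusted nulls, E[F] ~ inflation * df_corr * q~ scaled F mean."""
        rng = np.random.default_rng(25)
        d = ba.design_from_counts([[1, 5], [5, 1]])
        reps = 20_000
        Y = null_matrix(d, reps, rng)
        res = ba.oneway_f_test(ba.anova_adjust(Y, d), d)
        ap = ba.null_f_approx(d)
        dd = ap.df_denom
        predicted = ap.inflation * ap.df_correction * dd / (dd - 2)
        se = res["F"].std(ddof=1) / np.sqrt(reps)
        assert abs(res["F"].mean() - predicted) < 3 * se


class TestNullFApprox:
    def test_balanced_three_groups(self):
        d = ba.design_from_counts([[2, 2, 2], [2, 2, 2]])
        ap = ba.null_f_approx(d)
        np.testing.assert_allclose(ap.lambdas, [1.0, 1.0], atol=1e-10)
        assert ap.q_tilde == pytest.approx(2.0, abs=1e-10)
        assert ap.sigma_tilde_sq == pytest.approx(1.0, abs=1e-10)
        assert ap.inflation == pytest.approx(1.0, abs=1e-10)

    def test_seesaw_design_single_lambda(self, seesaw_design):
        ap = ba.null_f_approx(seesaw_design)
        np.testing.assert_allclose(ap.lambdas, [1.8], atol=1e-10)
        assert ap.q_tilde == pytest.approx(1.0, abs=1e-12)
        assert ap.inflation == pytest.approx(1.8, abs=1e-10)
        assert ap.df_correction == pytest.approx(1 + 1 / 9, abs=1e-12)

    def test_scale_invariance_of_lambdas(self, seesaw_design):
        d10 = ba.design_from_counts(seesaw_design.counts * 10)
        ap = ba.null_f_approx(d10)
        np.testing.assert_allclose(ap.lambdas, [1.8], atol=1e-8)
        assert ap.df_correction == pytest.approx(1 + 1 / 117, abs=1e-12)

    def test_m2_identity_sum_lambda_is_nu0_over_nu(self):
        """For two groups the eigenvalue sum equals the effective-sample-size
        over-confidence ratio, linking the F law to nu0/nu."""
        rng = np.random.default_rng(26)
        tested = 0
        while tested < 200:
            d = random_design(rng, M_max=2, connected=True)
            if d.M != 2:
                continue
            ess = ba.effective_sample_size(d, *d.groups)
            if ess.nu == 0:
                continue
            ap = ba.null_f_approx(d)
            assert ap.lambdas.sum() == pytest.approx(ess.ratio, abs=1e-8)
            tested += 1

    def test_satterthwaite_bounds(self):
        """q~ <= M-1 and q~ sigma~^2 >= M-1, equalities iff balanced."""
        rng = np.random.default_rng(27)
        tested = 0
        while tested < 100:
            d = random_design(rng, connected=True)
            if d.M < 2:
                continue
            ap = ba.null_f_approx(d)
            assert ap.q_tilde <= d.M - 1 + 1e-8
            assert ap.q_tilde * ap.sigma_tilde_sq >= d.M - 1 - 1e-8
            if d.is_proportional():
                assert ap.q_tilde == pytest.approx(d.M - 1, abs=1e-8)
                assert ap.inflation == pytest.approx(1.0, abs=1e-8)
            tested += 1

    def test_single_group_errors(self):
        d = ba.design_from_counts([[3], [3]])
        with pytest.raises(DesignError):
            ba.null_f_approx(d)


class TestCorrectedP:
    def test_zero_F_gives_p_one(self, seesaw_design):
        ap = ba.null_f_approx(seesaw_design)
        assert ba.corrected_p(0.0, ap) == pytest.approx(1.0)

    def test_negative_F_rejected(self, seesaw_design):
        ap = ba.null_f_approx(seesaw_design)
        with pytest.raises(ValueError):
            ba.corrected_p(-1.0, ap)

    def test_single_batch_limit_equals_naive(self):
        """With one batch the adjustment is a no-op and the corrected p is the
        plain one-way p on (M-1, n-M) df."""
        d = ba.design_from_counts([[4, 3, 5]])
        ap = ba.null_f_approx(d)
        assert ap.inflation == pytest.approx(1.0, abs=1e-10)
        assert ap.df_correction == pytest.approx(1.0)
        assert ap.df_denom == d.n - d.M
        F = np.array([0.5, 1.0, 3.7])
        np.testing.assert_allclose(
            ba.corrected_p(F, ap), st.f.sf(F, d.M - 1, d.n - d.M), atol=1e-10
        )

    def test_balanced_design_differs_only_by_df_correction(self):
        d = ba.design_from_counts([[3, 3], [3, 3]])
        ap = ba.null_f_approx(d)
        F = np.array([1.0, 2.5, 6.0])
        expected = st.f.sf(F / ap.df_correction, d.M - 1, ap.df_denom)
        np.testing.assert_allclose(ba.corrected_p(F, ap), expected, atol=1e-12)

    def test_restores_uniformity_on_adjusted_nulls(self, seesaw_design):
        rng = np.random.default_rng(28)
        reps = 20_000
        Y = null_matrix(seesaw_design, reps, rng)
        res = ba.oneway_f_test(ba.anova_adjust(Y, seesaw_design), seesaw_design)
        ap = ba.null_f_approx(seesaw_design)
        p = ba.corrected_p(res["F"].to_numpy(), ap)
        assert st.kstest(p, "uniform").statistic < 0.02
        # naive p clearly non-uniform
        assert st.kstest(res["p"].to_numpy(), "uniform").pvalue < 1e-10


class TestBhFdr:
    def test_closed_form_small_vector(self):
        np.testing.assert_allclose(
            ba.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], atol=1e-12
        )

    def test_all_ones(self):
        np.testing.assert_allclose(ba.bh_fdr([1.0, 1.0, 1.0]), 1.0, atol=0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ba.bh_fdr([0.5, 1.5])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(29)
        p = rng.uniform(size=500)
        q = ba.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_null_uniform_yields_no_discoveries(self):
        rng = np.random.default_rng(30)
        q = ba.bh_fdr(rng.uniform(size=10_000))
        assert (q < 0.05).sum() <= 5


class TestTwoStepTest:
    def test_table_contract_and_p_ordering(self, seesaw_design):
        rng = np.random.default_rng(31)
        Y = null_matrix(seesaw_design, 200, rng)
        table = ba.two_step_test(Y, seesaw_design, method="anova")
        assert list(table.columns) == [
            "feature", "F", "p_naive", "p_corrected", "q_naive", "q_corrected",
        ]
        # inflation > 1 and q~ <= M-1: the corrected p never understates
        assert (table["p_corrected"] >= table["p_naive"] - 1e-12).all()
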