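"""Group statistics: Welch t, chi-square, permutation tests, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fcnet import stats as st_mod


class TestWelch:
    def test_published_age_row(self):
        """Printed group summaries (38.00±11.85 n=30 vs 37.47±11.95 n=62)."""
        t, df, p = st_mod.welch_t_from_summary(38.00, 11.85, 30,
                                               37.47, 11.95, 62)
        assert t == pytest.approx(0.201, abs=0.01)
        assert p > 0.5

    def test_published_hamd_row(self):
        t, _, p = st_mod.welch_t_from_summary(2.93, 1.46, 30, 0.19, 0.51, 62)
        assert t == pytest.approx(9.987, abs=0.01)
        assert p < 0.001

    def test_published_education_row(self):
        t, _, _ = st_mod.welch_t_from_summary(14.07, 3.34, 30,
                                              15.42, 2.95, 62)
        assert t == pytest.approx(-1.889, abs=0.01)

    def test_equal_means_give_zero(self):
        t, _, p = st_mod.welch_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_raw_equals_summary_round_trip(self, rng):
        x = rng.normal(1.0, 2.0, size=25)
        y = rng.normal(0.0, 1.0, size=40)
        t_raw, df_raw, p_raw = st_mod.welch_t(x, y)
        t_sum, df_sum, p_sum = st_mod.welch_t_from_summary(
            x.mean(), x.std(ddof=1), 25, y.mean(), y.std(ddof=1), 40)
        assert t_raw == pytest.approx(t_sum, abs=1e-12)
        assert df_raw == pytest.approx(df_sum, abs=1e-9)
        assert p_raw == pytest.approx(p_sum, abs=1e-12)

    def test_scipy_cross_check(self, rng):
        from scipy.stats import ttest_ind

        x = rng.normal(size=20)
        y = rng.normal(size=30)
        t, df, p = st_mod.welch_t(x, y)
        ref = ttest_ind(x, y, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            st_mod.welch_t_from_summary(1.0, 0.0, 10, 2.0, 0.0, 10)


class TestChiSquare:
    def test_published_gender_table(self):
        chi2, p = st_mod.chi_square_2x2(15, 15, 26, 36)
        assert chi2 == pytest.approx(0.532, abs=1e-3)

    def test_proportional_rows_give_zero(self):
        chi2, _ = st_mod.chi_square_2x2(10, 20, 5, 10)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_separation(self):
        chi2, _ = st_mod.chi_square_2x2(10, 0, 0, 10)
        assert chi2 == pytest.approx(20.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            st_mod.chi_square_2x2(0, 0, 5, 5)


class TestNodalThreshold:
    def test_ninety_nodes(self):
        assert st_mod.nodal_threshold(90) == pytest.approx(0.011, abs=5e-4)

    @pytest.mark.parametrize("n,expect", [(1, 1.0), (200, 0.005)])
    def test_reciprocal(self, n, expect):
        assert st_mod.nodal_threshold(n) == pytest.approx(expect)


class TestResidualize:
    def test_no_covariates_mean_centers(self, rng):
        y = rng.normal(5, 2, size=30)
        r = st_mod.residualize(y, None)
        assert abs(r.mean()) < 1e-12
        np.testing.assert_allclose(r, y - y.mean())

    def test_exact_linear_function_vanishes(self, rng):
        c = rng.normal(size=(40, 3))
        y = c @ np.array([1.0, -2.0, 0.5]) + 3.0
        np.testing.assert_allclose(st_mod.residualize(y, c), 0.0, atol=1e-9)

    def test_noise_recovered_at_cohort_scale(self, rng):
        """Residualizing beta*age + noise on age returns essentially the noise.

        corr(residual, noise) = sqrt(1 - R^2_chance), ~0.994 in expectation
        at n=92; averaged over replicates to damp the per-draw chance R^2.
        """
        rs = []
        for _ in range(10):
            age = rng.normal(38, 12, size=92)
            noise = rng.normal(size=92)
            y = 0.1 * age + noise
            r = st_mod.residualize(y, age)
            rs.append(np.corrcoef(r, noise)[0, 1])
        assert min(rs) > 0.97
        assert np.mean(rs) > 0.99

    def test_idempotent(self, rng):
        c = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        once = st_mod.residualize(y, c)
        np.testing.assert_allclose(once, st_mod.residualize(once, c),
                                   atol=1e-10)

    def test_too_few_observations_rejected(self, rng):
        with pytest.raises(ValueError):
            st_mod.residualize(rng.normal(size=3), rng.normal(size=(3, 3)))


class TestPerThresholdGlobalTests:
    def test_identical_groups_give_null_results(self, rng):
        base = rng.normal(size=(4, 5))
        curves = {"Cp": np.vstack([base, base])}
        groups = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        out = st_mod.per_threshold_global_tests(
            curves, groups, np.linspace(0.1, 0.3, 5))
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p"], 1.0)

    def test_seven_metrics_twenty_thresholds_gives_140_rows(self, rng):
        grid = np.linspace(0.11, 0.30, 20)
        curves = {f"m{i}": rng.normal(size=(10, 20)) for i in range(7)}
        groups = np.zeros(10, dtype=bool)
        groups[:5] = True
        out = st_mod.per_threshold_global_tests(curves, groups, grid)
        assert len(out) == 140
        assert (out["correction"] == "uncorrected").all()


class TestPermutationTest:
    def test_identical_value_sets_give_p_near_one(self):
        vals = np.concatenate([np.arange(10.0), np.arange(10.0)])
        groups = np.array([True] * 10 + [False] * 10)
        res = st_mod.permutation_test_auc(vals, groups, n_perm=500, seed=0)
        assert res.observed == pytest.approx(0.0)
        assert res.p > 0.9

    def test_complete_separation_reaches_minimum_p(self):
        vals = np.concatenate([np.zeros(10), np.ones(10) * 100])
        groups = np.array([True] * 10 + [False] * 10)
        res = st_mod.permutation_test_auc(vals, groups, n_perm=499, seed=1)
        assert res.p == pytest.approx(1 / 500)

    def test_p_bounded_below_by_one_over_nplus1(self, rng):
        vals = rng.normal(size=30)
        groups = np.zeros(30, dtype=bool)
        groups[:12] = True
        res = st_mod.permutation_test_auc(vals, groups, n_perm=200, seed=2)
        assert res.p >= 1 / 201

    @given(st.floats(0.1, 50), st.floats(-5, 5))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_invariant_under_monotone_rescaling(self, scale, shift):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=24)
        groups = np.zeros(24, dtype=bool)
        groups[:10] = True
        p1 = st_mod.permutation_test_auc(vals, groups,
                                         n_perm=300, seed=5).p
        p2 = st_mod.permutation_test_auc(scale * vals + shift, groups,
                                         n_perm=300, seed=5).p
        assert p1 == p2

    def test_constant_values_warn_p_one(self):
        groups = np.array([True] * 5 + [False] * 5)
        with pytest.warns(UserWarning, match="constant"):
            res = st_mod.permutation_test_auc(np.ones(10), groups,
                                              n_perm=100, seed=0)
        assert res.p == 1.0

    def test_covariate_driven_difference_is_absorbed(self, rng):
        """A group difference explained entirely by age is not significant."""
        age = np.concatenate([rng.normal(50, 3, 15), rng.normal(30, 3, 15)])
        vals = 0.5 * age + rng.normal(0, 0.5, 30)
        groups = np.array([True] * 15 + [False] * 15)
        raw = st_mod.permutation_test_auc(vals, groups, None,
                                          n_perm=500, seed=3)
        adj = st_mod.permutation_test_auc(vals, groups, age,
                                          n_perm=500, seed=3)
        assert raw.p < 0.01
        assert adj.p > 0.05


class TestPartialCorrelation:
    def test_proportional_series_give_unit_r(self):
        x = np.arange(10.0)
        res = st_mod.partial_correlation_with_score(x, 3 * x + 1, None)
        assert res.r == pytest.approx(1.0)

    def test_independent_series_usually_weak(self, rng):
        hits = 0
        for _ in range(40):
            x = rng.normal(size=92)
            y = rng.normal(size=92)
            r = st_mod.partial_correlation_with_score(x, y, None).r
            hits += abs(r) < 0.3
        assert hits >= 38  # |r| < 0.3 in ~95% of replicates at n=92

    def test_confound_induced_correlation_removed(self, rng):
        age = rng.normal(40, 10, size=80)
        x = age + rng.normal(0, 1, 80)
        y = 2 * age + rng.normal(0, 1, 80)
        plain = st_mod.partial_correlation_with_score(x, y, None)
        partial = st_mod.partial_correlation_with_score(x, y, age)
        assert plain.r > 0.9
        assert abs(partial.r) < 0.3

    def test_significance_flag_uses_one_over_n(self):
        x = np.arange(20.0)
        res = st_mod.partial_correlation_with_score(
            x, x + np.random.default_rng(0).normal(0, 0.1, 20), None,
            n_nodes_for_threshold=90)
        assert res.significant_nodal  # p tiny, below 1/90

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            st_mod.partial_correlation_with_score(
                np.ones(10), np.arange(10.0), None)


class TestBetweenRegion:
    def test_region_with_itself_is_unity(self, rng):
        x = rng.normal(size=20)
        out = st_mod.between_region_correlation(x, x)
        assert out["all"][0] == pytest.approx(1.0)

    def test_independent_regions_mean_r_near_zero(self, rng):
        rs = [st_mod.between_region_correlation(
            rng.normal(size=30), rng.normal(size=30))["all"][0]
            for _ in range(50)]
        assert abs(np.mean(rs)) < 0.1

    def test_per_group_output(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(0, 0.5, size=20)
        groups = np.array(["IS"] * 10 + ["NIS"] * 10)
        out = st_mod.between_region_correlation(x, y, groups)
        assert set(out) == {"IS", "NIS"}

    def test_small_group_rejected(self, rng):
        groups = np.array(["IS"] * 3 + ["NIS"] * 7)
        with pytest.raises(ValueError, match="too small"):
            st_mod.between_region_correlation(
                rng.normal(size=10), rng.normal(size=10), groups)


class TestDemographicsTable:
    def test_table_shape_and_tests(self, tiny_cohort):
        tab = st_mod.demographics_table(tiny_cohort.cohort)
        assert len(tab) == 8
        assert (tab.loc[tab.measure == "Gender (male/female)", "test"]
                == "chi_square").all()
        assert set(tab.columns) >= {"measure", "IS", "NIS", "statistic", "p"}
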