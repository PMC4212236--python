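"""Differential-expression testing cascade: linear fit, F probabilities,
CDF shift test, Welch ANOVA and the per-feature classification flow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from mirtempo import (
    AnalysisConfig,
    CollapsedMatrix,
    assign_anova_groups,
    cdf_test,
    f_pvalue,
    fit_linear,
    nqt_transform,
    run_de_analysis,
    welch_anova,
)
from mirtempo.errors import (
    DegenerateDesignError,
    InvalidDfError,
    TooFewTimePointsError,
)
from mirtempo.normalization import NormalizedMatrix


class TestFitLinear:
    def test_exact_colinearity_flagged_perfect(self):
        fit = fit_linear([1.0, 2, 3], [1.0, 2, 3])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.perfect_fit and fit.p_value == 0.0

    def test_constant_y_no_trend(self):
        fit = fit_linear([2.0, 2, 2, 2], [1.0, 2, 3, 4])
        assert fit.slope == 0.0 and fit.f_statistic == 0.0 and fit.p_value == 1.0

    def test_hand_ols_example(self):
        fit = fit_linear([1.0, 3, 2, 4], [1.0, 2, 3, 4])
        assert fit.slope == pytest.approx(0.8)
        assert fit.intercept == pytest.approx(0.5)
        assert fit.f_statistic == pytest.approx(3.5556, abs=1e-3)
        assert fit.p_value == pytest.approx(stats.f.sf(fit.f_statistic, 1, 2))
        assert (fit.df_num, fit.df_den) == (1, 2)

    @pytest.mark.parametrize(
        "y, x",
        [([1.0, 2], [1.0, 2]), ([1.0, 2, 3], [1.0, 1, 2])],
    )
    def test_degenerate_designs_rejected(self, y, x):
        with pytest.raises(DegenerateDesignError):
            fit_linear(y, x)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_agrees_with_scipy_linregress(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(3, 12))
        x = np.sort(rng.uniform(0, 10, size=T))
        while np.any(np.diff(x) <= 0):
            x = np.sort(rng.uniform(0, 10, size=T))
        y = rng.normal(size=T)
        fit = fit_linear(y, x)
        ref = stats.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope, abs=1e-10)
        assert fit.intercept == pytest.approx(ref.intercept, abs=1e-10)
        # simple regression: F-test p equals the two-sided slope t-test p
        assert fit.p_value == pytest.approx(ref.pvalue, abs=1e-10)


class TestFPvalue:
    def test_zero_statistic_full_tail(self):
        assert f_pvalue(0.0, 1, 5) == 1.0

    def test_f11_symmetry_about_one(self):
        assert f_pvalue(1.0, 1, 1) == pytest.approx(0.5, abs=1e-12)

    def test_large_statistic_vanishes(self):
        assert f_pvalue(1e12, 1, 2) == pytest.approx(0.0, abs=1e-5)

    def test_invalid_df(self):
        with pytest.raises(InvalidDfError):
            f_pvalue(1.0, 0, 2)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_numeric_integration(self, seed):
        rng = np.random.default_rng(seed)
        f = float(rng.uniform(0, 8))
        df1 = int(rng.integers(1, 10))
        df2 = int(rng.integers(1, 10))
        oracle, err = quad(
            lambda u: stats.f.pdf(u, df1, df2), f, np.inf,
            limit=500, epsabs=1e-13, epsrel=1e-13,
        )
        assert err < 1e-10
        assert f_pvalue(f, df1, df2) == pytest.approx(oracle, abs=1e-10)


class TestCdfTest:
    def test_no_shift_gives_half(self):
        assert cdf_test(1.3, 1.3) == pytest.approx(0.5)

    def test_decrease_of_1_64_sigma_hits_alpha(self):
        assert cdf_test(0.0, -1.6449) == pytest.approx(0.05, abs=1e-3)

    def test_extreme_increase_saturates_at_one(self):
        assert cdf_test(0.0, 50.0) == pytest.approx(1.0)

    def test_two_sided_symmetric(self):
        assert cdf_test(0.0, 1.5, two_sided=True) == pytest.approx(
            cdf_test(0.0, -1.5, two_sided=True)
        )
        assert cdf_test(0.0, 1.5, two_sided=True) == pytest.approx(
            2 * stats.norm.sf(1.5)
        )

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-5, 5), st.floats(0.001, 3))
    def test_monotone_in_shift(self, d, eps):
        assert cdf_test(0.0, d) < cdf_test(0.0, d + eps)


class TestAnovaGroups:
    @pytest.mark.parametrize(
        "T, early, late",
        [(4, (1, 2), (3, 4)), (5, (1, 2), (3, 4, 5))],
    )
    def test_half_split(self, T, early, late):
        assert assign_anova_groups(T) == (early, late)

    @pytest.mark.parametrize("T", range(4, 21))
    def test_partition_property(self, T):
        a, b = assign_anova_groups(T)
        assert set(a) | set(b) == set(range(1, T + 1))
        assert not set(a) & set(b)
        assert len(a) >= 2 and len(b) >= 2

    def test_too_few_timepoints(self):
        with pytest.raises(TooFewTimePointsError):
            assign_anova_groups(3)


def _hand_welch(samples):
    """Independent evaluation of the k-group Welch formula."""
    k = len(samples)
    ns = np.array([len(s) for s in samples], float)
    means = np.array([np.mean(s) for s in samples])
    var = np.array([np.var(s, ddof=1) for s in samples])
    w = ns / var
    yw = np.sum(w * means) / np.sum(w)
    a = np.sum(w * (means - yw) ** 2) / (k - 1)
    lam = np.sum((1 - w / w.sum()) ** 2 / (ns - 1))
    f = a / (1 + 2 * (k - 2) / (k**2 - 1) * lam)
    df2 = (k**2 - 1) / (3 * lam)
    return float(stats.f.sf(f, k - 1, df2))


class TestWelchAnova:
    def test_identical_groups_p_one(self):
        y = np.array([1.0, 2, 3, 1, 2, 3])
        assert welch_anova(y, ((1, 2, 3), (4, 5, 6))) == 1.0

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=8)
        g = ((1, 2, 3, 4), (5, 6, 7, 8))
        assert welch_anova(y, g) == pytest.approx(
            welch_anova(y, (g[1], g[0])), abs=1e-12
        )

    def test_two_groups_equal_welch_t_test(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=10)
        g = ((1, 2, 3, 4, 5), (6, 7, 8, 9, 10))
        p_t = stats.ttest_ind(y[:5], y[5:], equal_var=False).pvalue
        assert welch_anova(y, g) == pytest.approx(p_t, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_hand_formula(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 8, size=2)
        y = rng.normal(size=n1 + n2) * rng.uniform(0.5, 3)
        g = (tuple(range(1, n1 + 1)), tuple(range(n1 + 1, n1 + n2 + 1)))
        want = _hand_welch([y[:n1], y[n1:]])
        assert welch_anova(y, g) == pytest.approx(want, abs=1e-10)


def _nm_from_values(values, mode="deterministic"):
    values = np.asarray(values, float)
    names = [f"f{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(names, values, rn=[], qt=[], mode=mode)


class TestRunDeAnalysis:
    def test_colinear_feature_is_linear_significant(self):
        nqt = np.array([[-1.0, 0.0, 1.0], [0.3, -0.1, 0.2]])
        cfg = AnalysisConfig(n_replicates=1, n_timepoints=3)
        res = run_de_analysis(_nm_from_values(nqt), cfg)
        assert res[0].classification == "linear_significant"
        assert res[0].linear.perfect_fit

    def test_two_timepoints_skip_linear_use_cdf(self):
        nqt = np.array([[1.0, -2.0], [0.0, 0.1]])
        cfg = AnalysisConfig(n_replicates=1, n_timepoints=2)
        res = run_de_analysis(_nm_from_values(nqt), cfg)
        assert all(r.linear is None for r in res)
        assert res[0].nonlinear.method == "CDF"
        # strong decrease: one-sided CDF p = Phi(-3) < alpha
        assert res[0].classification == "nonlinear_significant"
        assert res[1].classification == "not_significant"

    def test_three_timepoints_cdf_reports_both_comparisons(self):
        nqt = np.array([[0.0, 0.5, -0.5]])
        cfg = AnalysisConfig(n_replicates=1, n_timepoints=3)
        res = run_de_analysis(_nm_from_values(nqt), cfg)
        if res[0].classification != "linear_significant":
            assert set(res[0].nonlinear.cdf_pvals) == {"tp1_vs_tp2", "tp1_vs_tp3"}

    def test_many_timepoints_use_anova(self):
        rng = np.random.default_rng(5)
        nqt = rng.normal(size=(20, 6))
        cfg = AnalysisConfig(n_replicates=1, n_timepoints=6)
        res = run_de_analysis(_nm_from_values(nqt), cfg)
        nl = [r for r in res if r.nonlinear is not None]
        assert nl and all(r.nonlinear.method == "ANOVA" for r in nl)
        assert all(
            r.nonlinear.group_assignment == ((1, 2, 3), (4, 5, 6)) for r in nl
        )

    def test_every_feature_classified_and_sets_disjoint(self):
        rng = np.random.default_rng(6)
        nqt = rng.normal(size=(50, 4))
        cfg = AnalysisConfig(n_replicates=1, n_timepoints=4)
        res = run_de_analysis(_nm_from_values(nqt), cfg)
        assert len(res) == 50
        kinds = {"linear_significant", "nonlinear_significant", "not_significant"}
        assert all(r.classification in kinds for r in res)
        lin = {r.feature_name for r in res if r.classification == "linear_significant"}
        nl = {r.feature_name for r in res if r.classification == "nonlinear_significant"}
        assert not lin & nl

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(7)
        nqt = rng.normal(size=(100, 4))
        nm = _nm_from_values(nqt)
        sig = {}
        for alpha in (0.01, 0.05, 0.2):
            cfg = AnalysisConfig(n_replicates=1, n_timepoints=4, alpha=alpha)
            res = run_de_analysis(nm, cfg)
            sig[alpha] = {
                r.feature_name for r in res if r.classification != "not_significant"
            }
        assert sig[0.01] <= sig[0.05] <= sig[0.2]

    def test_bh_adjustment_never_grows_significant_set(self):
        rng = np.random.default_rng(8)
        nqt = rng.normal(size=(80, 5))
        nm = _nm_from_values(nqt)
        raw = run_de_analysis(
            nm, AnalysisConfig(n_replicates=1, n_timepoints=5)
        )
        adj = run_de_analysis(
            nm,
            AnalysisConfig(
                n_replicates=1, n_timepoints=5,
                multiple_testing="benjamini_hochberg",
            ),
        )
        raw_lin = {r.feature_name for r in raw if r.classification == "linear_significant"}
        adj_lin = {r.feature_name for r in adj if r.classification == "linear_significant"}
        assert adj_lin <= raw_lin

    def test_all_pvalues_in_unit_interval(self, null_dataset):
        from mirtempo import collapse_replicates

        m, _ = null_dataset
        cfg = AnalysisConfig(n_replicates=2, n_timepoints=4)
        nm = nqt_transform(collapse_replicates(m, 0.7), cfg)
        res = run_de_analysis(nm, cfg)
        for r in res:
            if r.linear is not None:
                assert 0.0 <= r.linear.p_value <= 1.0
            if r.nonlinear is not None:
                assert 0.0 <= r.nonlinear.min_p_value() <= 1.0
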