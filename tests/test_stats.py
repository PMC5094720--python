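"""Statistical layer: summaries, regression, ANOVA, Kruskal-Wallis,
normality grading and the trend table."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from nanoxrf.stats import (
    TimeCourse,
    anova_oneway,
    build_trend_table,
    group_summary,
    kruskal_wallis,
    normality_grade,
    regression_residuals,
    time_regression,
)


def ols_normal_equations(x, y):
    """Independent closed-form OLS oracle."""
    x = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(x.T @ x, x.T @ y)
    resid = y - x @ beta
    ss_res = resid @ resid
    ss_tot = np.sum((y - y.mean()) ** 2)
    return beta, 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


class TestGroupSummary:
    def test_identical_values_have_zero_rsd(self):
        mean, sd, n, flag = group_summary([2.0, 2.0, 2.0])
        assert (mean, sd, n, flag) == (2.0, 0.0, 3, False)

    def test_table_scale_example(self):
        # {1.26, 1.40, 1.54}: mean 1.40, sd 0.14, within the 25% band
        mean, sd, n, flag = group_summary([1.26, 1.40, 1.54])
        assert mean == pytest.approx(1.40)
        assert sd == pytest.approx(0.14)
        assert not flag

    def test_wide_pair_flagged_italic(self):
        mean, sd, _, flag = group_summary([1.0, 2.0])
        assert mean == 1.5
        assert sd == pytest.approx(math.sqrt(0.5))
        assert flag  # 47% > 25%

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])


class TestTimeRegression:
    def test_perfect_line_exact_slope_unit_r2(self):
        tc = TimeCourse("X", "entire_cell", [0, 1, 2], [2e-9, 4e-9, 6e-9])
        slope, r2, ci, trend = time_regression(tc)
        assert slope == pytest.approx(2.0, rel=1e-9)  # ppb/h
        assert r2 == pytest.approx(1.0)
        assert ci[1] - ci[0] == pytest.approx(0.0, abs=1e-6)
        assert trend == "+"

    def test_three_point_closed_form(self):
        tc = TimeCourse("X", "entire_cell", [0, 1, 2], [0.0, 1e-9, 1e-9])
        slope, r2, _, _ = time_regression(tc)
        assert slope == pytest.approx(0.5, rel=1e-9)
        assert r2 == pytest.approx(0.75, rel=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            t = np.repeat([0.0, 1.0, 2.0], [3, 3, 2])
            y = np.abs(rng.normal(1e-5, 3e-6, t.size))
            tc = TimeCourse("X", "nucleus", t, y)
            slope, r2, _, _ = time_regression(tc)
            beta, r2_o = ols_normal_equations(t, y)
            assert slope * 1e-9 == pytest.approx(beta[1], rel=1e-10, abs=1e-18)
            assert r2 == pytest.approx(r2_o, rel=1e-10)

    def test_slope_recovery_and_ci_coverage_at_study_design(self):
        """500 simulated time courses at n = 3/3/2 with a P-scale slope
        (1.13e7 ppb/h): mean recovered slope within 2 SEM, 95% CI coverage
        in [90%, 98%]."""
        beta_true = 1.13e7  # ppb/h
        rng = np.random.default_rng(11)
        t = np.repeat([0.0, 1.0, 2.0], [3, 3, 2])
        slopes, covered = [], 0
        n_sim = 500
        for _ in range(n_sim):
            y = 0.014 + beta_true * 1e-9 * t + rng.normal(0.0, 0.004, t.size)
            tc = TimeCourse("P", "entire_cell", t, np.abs(y))
            slope, _, ci, _ = time_regression(tc)
            slopes.append(slope)
            if ci[0] <= beta_true <= ci[1]:
                covered += 1
        slopes = np.asarray(slopes)
        sem = slopes.std() / math.sqrt(n_sim)
        assert abs(slopes.mean() - beta_true) < 2 * sem
        assert 0.90 <= covered / n_sim <= 0.98

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            time_regression(TimeCourse("X", "c", [1.0, 1.0, 1.0], [1e-9, 2e-9, 3e-9]))
        with pytest.raises(ValueError):
            time_regression(TimeCourse("X", "c", [0.0, 1.0], [1e-9, 2e-9]))


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        f, p = anova_oneway([np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0])])
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_group_example(self):
        f, p = anova_oneway([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        assert f == pytest.approx(13.5, rel=1e-9)

    def test_identical_values_return_f0_p1(self):
        f, p = anova_oneway([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert (f, p) == (0.0, 1.0)

    def test_two_group_f_equals_t_squared(self):
        """t^2 = F identity over 100 random datasets (pooled-variance t)."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(0, 1, rng.integers(3, 8))
            b = rng.normal(0.5, 1, rng.integers(3, 8))
            f, _ = anova_oneway([a, b])
            t, _ = sps.ttest_ind(a, b, equal_var=True)
            assert f == pytest.approx(t**2, rel=1e-9)

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 4) for _ in range(3)]
        f0, _ = anova_oneway(groups)
        f1, _ = anova_oneway([3.0 * g + 7.0 for g in groups])
        assert f1 == pytest.approx(f0, rel=1e-9)

    def test_type_one_error_near_nominal_at_study_design(self):
        """Null ANOVA at n = 3/3/2: rejection rate at alpha = 0.05 stays in
        [0.03, 0.08] over 10^4 simulations (documents small-sample level)."""
        rng = np.random.default_rng(8)
        sizes = (3, 3, 2)
        # vectorized classical one-way F over all simulations at once
        n_sim = 10_000
        data = [rng.normal(0.0, 1.0, (n_sim, s)) for s in sizes]
        n = sum(sizes)
        grand = np.concatenate(data, axis=1).mean(axis=1)
        ss_between = sum(s * (d.mean(axis=1) - grand) ** 2 for s, d in zip(sizes, data))
        ss_within = sum(((d - d.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) for d in data)
        f = (ss_between / 2) / (ss_within / (n - 3))
        p = sps.f.sf(f, 2, n - 3)
        # cross-check vectorization against the implementation on one draw
        f0, p0 = anova_oneway([d[0] for d in data])
        assert f0 == pytest.approx(f[0], rel=1e-9)
        rate = float(np.mean(p < 0.05))
        assert 0.03 <= rate <= 0.08


class TestKruskalWallis:
    def test_identical_values_give_zero(self):
        h, p = kruskal_wallis([np.array([1.0, 1.0]), np.array([1.0, 1.0])])
        assert (h, p) == (0.0, 1.0)

    def test_rank_formula_hand_example(self):
        """{1,2} vs {3,4}: H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2 = 2.4."""
        h, _ = kruskal_wallis([np.array([1.0, 2.0]), np.array([3.0, 4.0])])
        # independent rank arithmetic: ranks 1,2 | 3,4; Rbar = 2.5
        oracle = 12.0 / (4 * 5) * (2 * (1.5 - 2.5) ** 2 + 2 * (3.5 - 2.5) ** 2)
        assert oracle == pytest.approx(2.4)
        assert h == pytest.approx(oracle, rel=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(0, 1, 4) for _ in range(3)]
        h0, _ = kruskal_wallis(groups)
        h1, _ = kruskal_wallis([np.exp(g) for g in groups])
        assert h1 == pytest.approx(h0, rel=1e-9)

    def test_exact_permutation_p_close_to_asymptotic_for_small_n(self):
        """Exhaustive permutation null at N = 8 agrees with the asymptotic p
        to within the chi-square approximation error."""
        groups = [
            np.array([1.0, 2.0, 5.0]),
            np.array([3.0, 7.0, 8.0]),
            np.array([4.0, 6.0]),
        ]
        h_asym, p_asym = kruskal_wallis(groups)
        h_exact, p_exact = kruskal_wallis(groups, permutation=True)
        assert h_exact == pytest.approx(h_asym, rel=1e-9)
        assert 0.0 < p_exact < 1.0
        assert abs(p_exact - p_asym) < 0.15

    def test_exact_p_matches_brute_force_count(self):
        """Permutation p equals a direct enumeration oracle for tiny N."""
        from itertools import permutations

        from nanoxrf.stats import _kw_statistic

        groups = [np.array([1.0, 4.0]), np.array([2.0, 3.0])]
        _, p = kruskal_wallis(groups, permutation=True)
        allv = np.concatenate(groups)
        h_obs = _kw_statistic(groups)
        count = sum(
            _kw_statistic([np.array(perm[:2]), np.array(perm[2:])]) >= h_obs - 1e-12
            for perm in permutations(allv)
        )
        assert p == pytest.approx(count / math.factorial(4))


class TestNormalityGrade:
    def test_gaussian_residuals_grade_best(self):
        rng = np.random.default_rng(12)
        grade, r = normality_grade(rng.normal(0, 1, 1000))
        assert grade == "+++"
        assert r > 0.99

    def test_two_point_staircase_grades_worst(self):
        resid = np.array([-1.0] * 10 + [1.0] * 10)
        grade, r = normality_grade(resid)
        assert grade == "+"

    def test_symmetric_three_point_set_is_deterministic(self):
        # {-1, 0, 1}: both axes equally spaced -> r = 1 exactly
        grade, r = normality_grade(np.array([-1.0, 0.0, 1.0]))
        assert r == pytest.approx(1.0, abs=1e-12)
        assert grade == "+++"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normality_grade(np.zeros(5))

    def test_hazen_positions_available(self):
        rng = np.random.default_rng(13)
        resid = rng.normal(0, 1, 50)
        g_blom, r_blom = normality_grade(resid, plotting_positions="blom")
        g_hazen, r_hazen = normality_grade(resid, plotting_positions="hazen")
        assert abs(r_blom - r_hazen) < 0.02


class TestTrendTable:
    def _tc(self, element, values, comp="entire_cell"):
        t = np.repeat([0.0, 1.0, 2.0], [3, 3, 2])
        return TimeCourse(element, comp, t, np.asarray(values))

    def test_low_r2_row_suppresses_slope_and_ci(self):
        # equal group means with within-group scatter: r2 near zero
        tc = self._tc("K", 1e-6 * np.array([10, 14, 12, 13, 11, 12, 12.5, 11.5]))
        table = build_trend_table([tc])
        row = table.iloc[0]
        assert row["r2"] < 0.5
        assert np.isnan(row["beta0_ppb_per_h"])
        assert np.isnan(row["ci95_lo"])
        assert not row["bold"]

    def test_strong_trend_row_reports_slope_in_bold(self):
        values = 1e-9 * np.array([1, 1.1, 0.9, 3, 3.1, 2.9, 5, 5.1])
        table = build_trend_table([self._tc("P", values)])
        row = table.iloc[0]
        assert row["r2"] >= 0.5
        assert row["bold"]
        assert row["beta0_ppb_per_h"] == pytest.approx(2.0, rel=0.1)

    def test_kw_runs_only_for_least_normal_rows(self):
        rng = np.random.default_rng(21)
        staircase = 1e-9 * np.array([1, 1, 1, 2, 2, 2, 3, 3.0])
        noisy = np.abs(rng.normal(1e-6, 2e-7, 8))
        table = build_trend_table(
            [self._tc("Cl", staircase), self._tc("K", noisy)]
        )
        graded_plus = table["normality_grade"] == "+"
        assert table.loc[graded_plus, "kw_chi2"].notna().all()
        assert table.loc[~graded_plus, "kw_chi2"].isna().all()

    def test_full_grid_dimensions(self):
        rng = np.random.default_rng(22)
        tcs = [
            self._tc(el, np.abs(rng.normal(1e-6, 3e-7, 8)), comp)
            for el in ("P", "S", "Cl")
            for comp in ("entire_cell", "nucleus", "cytoplasm")
        ]
        table = build_trend_table(tcs)
        assert len(table) == 9
        assert set(table["compartment"]) == {"entire_cell", "nucleus", "cytoplasm"}

    def test_residuals_standardized(self):
        tc = self._tc("P", 1e-9 * np.arange(1.0, 9.0))
        resid = regression_residuals(tc)
        assert resid.std(ddof=1) == pytest.approx(1.0) or np.allclose(resid, 0)
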