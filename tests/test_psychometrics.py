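import numpy as np
import pandas as pd
import pytest

from dsitext.errors import InvalidInputError, InvalidParameterError, UndefinedStatisticError
from dsitext.psychometrics import (
    cohens_d_from_stats,
    compare_dependent_correlations,
    compare_independent_correlations,
    fisher_ci,
    group_comparison,
    hierarchical_regression,
    icc,
    omega_single_factor,
    pearson_ci,
    single_rater_average,
)


class TestPearsonCI:
    def test_fisher_bounds_at_published_n(self):
        ci = fisher_ci(0.77, 179)
        assert round(ci.ci_low, 2) == 0.70
        assert round(ci.ci_high, 2) == 0.82

    def test_perfect_correlation_degenerate(self):
        x = np.arange(10.0)
        ci = pearson_ci(x, x)
        assert ci.r == pytest.approx(1.0)
        assert ci.ci_low == ci.ci_high == ci.r

    def test_orthogonal_symmetric_about_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        ci = pearson_ci(x, y)
        assert ci.r == pytest.approx(0.0, abs=1e-12)
        assert ci.ci_low == pytest.approx(-ci.ci_high)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_ci(np.ones(10), np.arange(10.0))

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(50)
        y = x + rng.standard_normal(50)
        a = pearson_ci(x, y)
        b = pearson_ci(3.2 * x + 7, 0.5 * y - 2)
        assert a.r == pytest.approx(b.r)
        assert a.ci_low == pytest.approx(b.ci_low)


class TestDependentComparison:
    def test_equal_correlations_z_zero(self):
        res = compare_dependent_correlations(0.6, 0.6, 0.4, 100)
        assert res.z == pytest.approx(0.0)
        assert res.diff == pytest.approx(0.0)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_dependent_correlations(0.9, -0.9, 0.9, 100)

    def test_small_n_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_dependent_correlations(0.5, 0.3, 0.2, 5)

    def test_null_calibration_by_simulation(self):
        # parametric oracle: both predictors equally correlated with y
        rho, r12, n, reps = 0.65, 0.6, 200, 3000
        R = np.array([[1.0, r12, rho], [r12, 1.0, rho], [rho, rho, 1.0]])
        L = np.linalg.cholesky(R)
        rng = np.random.default_rng(42)
        rejections = 0
        for _ in range(reps):
            X = rng.standard_normal((n, 3)) @ L.T
            C = np.corrcoef(X, rowvar=False)
            res = compare_dependent_correlations(C[0, 2], C[1, 2], C[0, 1], n)
            rejections += res.p < 0.05
        assert abs(rejections / reps - 0.05) < 0.02

    def test_ci_brackets_difference(self):
        res = compare_dependent_correlations(0.8, 0.5, 0.6, 200)
        assert res.ci_low < res.diff < res.ci_high
        assert res.p < 0.05


class TestIndependentComparison:
    def test_published_group_values(self):
        res = compare_independent_correlations(0.66, 107, 0.52, 119)
        assert round(res.z, 2) == 1.60
        assert res.diff == pytest.approx(0.14)

    def test_equal_correlations(self):
        assert compare_independent_correlations(0.4, 50, 0.4, 60).z == pytest.approx(0.0)

    def test_swap_negates_z(self):
        a = compare_independent_correlations(0.66, 107, 0.52, 119)
        b = compare_independent_correlations(0.52, 119, 0.66, 107)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_small_n_rejected(self):
        with pytest.raises(InvalidInputError):
            compare_independent_correlations(0.5, 3, 0.4, 50)


class TestSingleRaterAverage:
    def test_identical_raters(self, rng):
        col = rng.standard_normal(30)
        ratings = pd.DataFrame({"r1": col, "r2": col, "r3": col})
        assert single_rater_average(ratings) == pytest.approx(1.0)

    def test_two_independent_raters_closed_form(self):
        # two raters of pure independent noise: each correlates with the
        # including-self mean at sqrt(1/2)
        rng = np.random.default_rng(1)
        ratings = pd.DataFrame(rng.standard_normal((10000, 2)), columns=["a", "b"])
        assert single_rater_average(ratings) == pytest.approx(np.sqrt(0.5), abs=0.02)

    def test_constant_rater_excluded_with_warning(self, rng):
        ratings = pd.DataFrame(
            {"a": rng.standard_normal(30), "b": rng.standard_normal(30), "c": np.ones(30)}
        )
        with pytest.warns(UserWarning, match="zero variance"):
            value = single_rater_average(ratings)
        assert np.isfinite(value)

    def test_leave_one_out_lower(self, rng):
        base = rng.standard_normal(500)
        ratings = pd.DataFrame(
            {f"r{j}": base + rng.standard_normal(500) for j in range(3)}
        )
        assert single_rater_average(ratings, leave_one_out=True) < single_rater_average(ratings)

    def test_single_rater_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            single_rater_average(pd.DataFrame({"a": rng.standard_normal(10)}))


def one_factor_sample(loadings, n, seed):
    rng = np.random.default_rng(seed)
    lam = np.asarray(loadings)
    factor = rng.standard_normal(n)
    noise = rng.standard_normal((n, lam.size)) * np.sqrt(1 - lam**2)
    return factor[:, None] * lam[None, :] + noise


class TestOmega:
    def test_equal_loadings_near_closed_form(self):
        # population omega for 7 indicators loading .8: 5.6^2/(5.6^2+7*.36)
        X = one_factor_sample([0.8] * 7, 8000, seed=3)
        expected = 5.6**2 / (5.6**2 + 7 * 0.36)
        assert omega_single_factor(X) == pytest.approx(expected, abs=0.02)

    def test_identical_indicators_heywood(self, rng):
        col = rng.standard_normal(100)
        X = np.column_stack([col, col, col])
        with pytest.warns(UserWarning, match="Heywood"):
            value = omega_single_factor(X)
        assert value > 0.99

    def test_independent_indicators_near_zero(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((4000, 5))
        assert omega_single_factor(X) < 0.15

    def test_too_few_indicators(self, rng):
        with pytest.raises(InvalidInputError):
            omega_single_factor(rng.standard_normal((50, 2)))


class TestICC:
    def test_identical_raters(self, rng):
        col = rng.standard_normal(40)
        res = icc(pd.DataFrame({"a": col, "b": col, "c": col}))
        assert res.single == pytest.approx(1.0)
        assert res.average == pytest.approx(1.0)

    def test_pure_noise_near_zero(self):
        rng = np.random.default_rng(5)
        res = icc(pd.DataFrame(rng.standard_normal((5000, 4))))
        assert abs(res.single) < 0.03

    def test_average_at_least_single(self, rng):
        base = rng.standard_normal(60)
        ratings = pd.DataFrame({f"r{j}": base + 0.8 * rng.standard_normal(60) for j in range(4)})
        res = icc(ratings)
        assert res.average >= res.single > 0

    def test_matches_pingouin_oracle(self, rng):
        pingouin = pytest.importorskip("pingouin")
        base = rng.standard_normal(30)
        ratings = pd.DataFrame({f"r{j}": base + rng.standard_normal(30) for j in range(3)})
        long = ratings.reset_index().melt(id_vars="index", var_name="rater", value_name="score")
        table = pingouin.intraclass_corr(long, targets="index", raters="rater", ratings="score")
        res = icc(ratings)
        by_type = table.set_index("Type")["ICC"]
        single = by_type.get("ICC2", by_type.get("ICC(A,1)"))
        average = by_type.get("ICC2k", by_type.get("ICC(A,k)"))
        assert res.single == pytest.approx(single, abs=1e-8)
        assert res.average == pytest.approx(average, abs=1e-8)

    def test_too_small(self, rng):
        with pytest.raises(InvalidInputError):
            icc(pd.DataFrame({"a": [1.0, 2.0]}))


class TestHierarchicalRegression:
    def test_exact_fit_step1(self, rng):
        x1 = rng.standard_normal(60)
        x2 = rng.standard_normal(60)
        res = hierarchical_regression(
            x1, pd.DataFrame({"x1": x1}), pd.DataFrame({"x2": x2}), n_boot=100, seed=0
        )
        assert res.step1.r2 == pytest.approx(1.0)
        assert res.delta_r2 == pytest.approx(0.0, abs=1e-12)

    def test_orthonormal_decomposition(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 + x2
        res = hierarchical_regression(
            y, pd.DataFrame({"x1": x1}), pd.DataFrame({"x2": x2}), n_boot=100, seed=0
        )
        assert res.delta_r2 == pytest.approx(res.step2.r2 - res.step1.r2)
        assert res.step2.r2 == pytest.approx(1.0)

    def test_standardized_recovery(self):
        rng = np.random.default_rng(11)
        n = 5000
        z1, z2 = rng.standard_normal(n), rng.standard_normal(n)
        y = 0.3 * z1 + 0.6 * z2 + rng.standard_normal(n) * np.sqrt(1 - 0.09 - 0.36)
        res = hierarchical_regression(
            y, pd.DataFrame({"z1": z1}), pd.DataFrame({"z2": z2}), n_boot=200, seed=1
        )
        assert res.step2.coefficients.loc["z1", "b_std"] == pytest.approx(0.3, abs=0.03)
        assert res.step2.coefficients.loc["z2", "b_std"] == pytest.approx(0.6, abs=0.03)

    def test_r2_monotone(self, rng):
        y = rng.standard_normal(80)
        res = hierarchical_regression(
            y,
            pd.DataFrame(rng.standard_normal((80, 3)), columns=list("abc")),
            pd.DataFrame(rng.standard_normal((80, 2)), columns=list("de")),
            n_boot=100,
            seed=0,
        )
        assert res.step2.r2 >= res.step1.r2

    def test_collinearity_detected(self, rng):
        x = rng.standard_normal(50)
        with pytest.raises(InvalidInputError, match="collinearity"):
            hierarchical_regression(
                rng.standard_normal(50),
                pd.DataFrame({"x1": x, "x2": 2 * x}),
                pd.DataFrame({"x3": rng.standard_normal(50)}),
                n_boot=10,
            )

    def test_delta_ci_deterministic_given_seed(self, rng):
        y = rng.standard_normal(60)
        X1 = pd.DataFrame({"a": rng.standard_normal(60)})
        X2 = pd.DataFrame({"b": rng.standard_normal(60)})
        r1 = hierarchical_regression(y, X1, X2, n_boot=200, seed=7)
        r2 = hierarchical_regression(y, X1, X2, n_boot=200, seed=7)
        assert r1.delta_r2_ci == r2.delta_r2_ci


class TestGroupComparison:
    def test_published_summary_stats(self):
        res = cohens_d_from_stats(4.50, 1.80, 107, 3.42, 1.56, 119)
        assert round(res.d, 2) == 0.64
        assert res.p < 0.001

    def test_identical_groups(self, rng):
        x = rng.standard_normal(40)
        res = group_comparison(x, x)
        assert res.t == pytest.approx(0.0)
        assert res.d == pytest.approx(0.0)

    def test_swap_negates(self, rng):
        a = rng.standard_normal(40)
        b = rng.standard_normal(45) + 0.5
        ab, ba = group_comparison(a, b), group_comparison(b, a)
        assert ab.t == pytest.approx(-ba.t)
        assert ab.d == pytest.approx(-ba.d)

    def test_raw_equals_summary_formula(self, rng):
        a = rng.standard_normal(30) + 1.0
        b = rng.standard_normal(35)
        raw = group_comparison(a, b)
        summ = cohens_d_from_stats(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert raw.t == pytest.approx(summ.t)
        assert raw.d == pytest.approx(summ.d)
        assert raw.df == pytest.approx(summ.df)

    def test_zero_variance_both_groups(self):
        with pytest.raises(UndefinedStatisticError):
            group_comparison(np.ones(10), np.ones(12))


def test_independent_comparison_null_calibration_small():
    # smaller version of the acceptance calibration check
    rng = np.random.default_rng(3)
    n, reps, rho = 60, 2000, 0.3
    L = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
    rejections = 0
    for _ in range(reps):
        XA = rng.standard_normal((n, 2)) @ L.T
        XB = rng.standard_normal((n, 2)) @ L.T
        rA = np.corrcoef(XA, rowvar=False)[0, 1]
        rB = np.corrcoef(XB, rowvar=False)[0, 1]
        rejections += compare_independent_correlations(rA, n, rB, n).p < 0.05
    assert abs(rejections / reps - 0.05) < 0.02
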