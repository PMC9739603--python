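import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fwbench.features import FeatureMatrix
from fwbench.regression import (
    correlation_filter,
    cosine_correlation,
    default_lambda_grid,
    fit_lasso,
    fit_linear,
    kkt_residual,
    lambda_max,
    lasso_path,
    standardize,
)


def _fm(columns: dict[str, list[int]]) -> FeatureMatrix:
    names = list(columns)
    counts = np.column_stack([columns[n] for n in names])
    ids = [f"L{i}" for i in range(counts.shape[0])]
    return FeatureMatrix(ids, names, counts)


def _objective(X, y, beta, intercept, lam, flags=None):
    n = len(y)
    r = y - intercept - X @ beta
    pen = np.abs(beta) if flags is None else np.abs(beta) * np.array(flags)
    return r @ r / n + lam * pen.sum()


class TestCosineCorrelation:
    def test_identical_vectors(self):
        a = np.array([3.0, 1.0, 4.0])
        assert cosine_correlation(a, a) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_correlation([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)

    def test_hand_computed(self):
        # a.b = 8, |a| = |b| = 3
        assert cosine_correlation([1, 2, 2], [2, 1, 2]) == pytest.approx(8 / 9)

    def test_symmetric(self):
        a, b = [1, 2, 3], [0, 1, 5]
        assert cosine_correlation(a, b) == cosine_correlation(b, a)

    def test_uncentered_differs_from_pearson(self):
        a, b = [1, 2, 3], [4, 5, 7]
        assert cosine_correlation(a, b) != pytest.approx(
            cosine_correlation(a, b, centered=True))

    def test_pearson_variant(self):
        a, b = [1.0, 2, 3, 4], [2.0, 4, 6, 8.5]
        assert cosine_correlation(a, b, centered=True) == pytest.approx(
            np.corrcoef(a, b)[0, 1])

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_correlation([0, 0], [1, 2])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            cosine_correlation([1, 2], [1, 2, 3])

    @given(st.lists(st.integers(0, 10), min_size=2, max_size=20),
           st.floats(0.1, 100.0))
    def test_scale_invariance(self, counts, scale):
        a = np.array(counts, dtype=float)
        if np.linalg.norm(a) == 0:
            return
        assert cosine_correlation(a, scale * a) == pytest.approx(1.0)


class TestCorrelationFilter:
    def test_duplicate_column_drops_rarer(self):
        # A occurs in 4 ligands, B (proportional, r=1) in 3
        fm = _fm({"A": [1, 2, 1, 1, 0], "B": [1, 2, 1, 0, 0],
                  "C": [0, 0, 1, 0, 3]})
        fm.counts[:, 1] = fm.counts[:, 0] * [1, 1, 1, 0, 1]  # keep r high
        filtered, report = correlation_filter(fm, 0.9)
        dropped = [r.dropped for r in report]
        assert "B" in dropped
        assert "A" in filtered.feature_names

    def test_exact_duplicate_occurrence_tiebreak(self):
        fm = _fm({"A": [1, 2, 1, 0], "B": [1, 2, 1, 0], "C": [0, 1, 0, 2]})
        filtered, report = correlation_filter(fm, 0.9)
        assert [r.dropped for r in report] == ["B"]
        assert report[0].kept == "A"
        assert report[0].r == pytest.approx(1.0)

    def test_no_high_pairs_is_identity(self):
        fm = _fm({"A": [1, 0, 0, 2], "B": [0, 3, 0, 0], "C": [0, 0, 1, 0]})
        filtered, report = correlation_filter(fm, 0.9)
        assert filtered.feature_names == ["A", "B", "C"]
        assert report == []

    def test_three_identical_columns_one_survives(self):
        col = [1, 0, 2, 1]
        fm = _fm({"A": col, "B": col, "C": col, "D": [0, 5, 0, 0]})
        filtered, report = correlation_filter(fm, 0.9)
        survivors = [n for n in filtered.feature_names if n in "ABC"]
        assert survivors == ["A"]
        assert len([r for r in report if r.reason == "correlated"]) == 2

    def test_no_surviving_pair_above_threshold(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(2.0, size=(50, 6))
        base[:, 3] = base[:, 0]  # inject a duplicate
        fm = FeatureMatrix([f"L{i}" for i in range(50)],
                           list("ABCDEF"), base)
        filtered, _ = correlation_filter(fm, 0.9)
        for i, a in enumerate(filtered.feature_names):
            for b in filtered.feature_names[i + 1:]:
                assert cosine_correlation(fm.column(a), fm.column(b)) <= 0.9

    def test_all_zero_column_removed_with_report(self):
        fm = _fm({"A": [1, 0, 2], "B": [0, 0, 0], "C": [0, 1, 0]})
        filtered, report = correlation_filter(fm, 0.9)
        assert "B" not in filtered.feature_names
        zero = [r for r in report if r.reason == "all_zero"]
        assert [r.dropped for r in zero] == ["B"]

    def test_bad_threshold_rejected(self):
        fm = _fm({"A": [1, 0], "B": [0, 1]})
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError, match="threshold"):
                correlation_filter(fm, bad)


class TestStandardize:
    def test_hand_computed_column(self):
        fm = _fm({"A": [0, 1, 2]})
        z = standardize(fm)
        np.testing.assert_allclose(
            z.values[:, 0], [-1.22474487, 0.0, 1.22474487], atol=1e-8)
        assert z.means[0] == pytest.approx(1.0)
        assert z.sds[0] == pytest.approx(0.81649658)  # population sd

    def test_columns_have_zero_mean_unit_sd(self):
        fm = _fm({"A": [0, 1, 5, 2], "B": [3, 0, 0, 1]})
        z = standardize(fm)
        np.testing.assert_allclose(z.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.values.std(axis=0), 1.0, atol=1e-10)

    def test_idempotent_on_standardized_data(self):
        fm = _fm({"A": [0, 1, 5, 2], "B": [3, 0, 0, 1]})
        z = standardize(fm)
        again = (z.values - z.values.mean(axis=0)) / z.values.std(axis=0)
        np.testing.assert_allclose(again, z.values, atol=1e-12)

    def test_inverse_transform_identity(self):
        fm = _fm({"A": [0, 1, 5, 2], "B": [3, 0, 0, 1]})
        z = standardize(fm)
        np.testing.assert_allclose(z.inverse(), fm.counts.astype(float),
                                   atol=1e-10)

    def test_constant_column_rejected(self):
        fm = _fm({"A": [2, 2, 2], "B": [0, 1, 2]})
        with pytest.raises(ValueError, match="constant"):
            standardize(fm)


def _random_problem(rng, n=30, p=6, sparse=True):
    X = rng.normal(size=(n, p))
    beta = np.zeros(p)
    beta[: p // 2] = rng.normal(size=p // 2) if sparse else 0.0
    y = 2.0 + X @ beta + 0.3 * rng.normal(size=n)
    return X, y


class TestFitLasso:
    def test_lambda_zero_equals_ols(self, rng):
        X, y = _random_problem(rng)
        fit = fit_lasso(X, y, 0.0)
        Xd = np.column_stack([np.ones(len(y)), X])
        ref = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert fit.intercept == pytest.approx(ref[0], abs=1e-8)
        np.testing.assert_allclose(
            [fit.coefficients[f"x{j}"] for j in range(X.shape[1])],
            ref[1:], atol=1e-8)

    def test_above_lambda_max_all_zero(self, rng):
        X, y = _random_problem(rng)
        lam = lambda_max(X, y)
        for factor in (1.0, 1.5, 10.0):
            fit = fit_lasso(X, y, lam * factor)
            assert all(v == 0.0 for v in fit.coefficients.values())
            assert fit.intercept == pytest.approx(y.mean())

    def test_orthonormal_soft_threshold_closed_form(self, rng):
        n, p = 30, 6
        raw = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))  # centered orthonormal
        y = 1.0 + rng.normal(size=n)
        lam = 0.05
        fit = fit_lasso(Q, y, lam)
        z = Q.T @ (y - y.mean())
        expected = np.sign(z) * np.maximum(np.abs(z) - n * lam / 2.0, 0.0)
        np.testing.assert_allclose(
            [fit.coefficients[f"x{j}"] for j in range(p)], expected,
            atol=1e-6)

    def test_kkt_residual_small(self, rng):
        for _ in range(5):
            X, y = _random_problem(rng)
            lam = 0.5 * lambda_max(X, y)
            fit = fit_lasso(X, y, lam)
            assert fit.converged
            assert kkt_residual(X, y, fit) <= 1e-6

    def test_unpenalized_column_exempt(self, rng):
        X, y = _random_problem(rng)
        lam = 2.0 * lambda_max(X, y)
        flags = [True] * (X.shape[1] - 1) + [False]
        fit = fit_lasso(X, y, lam, flags)
        # penalized columns die, the exempt one stays at its partial OLS value
        for j in range(X.shape[1] - 1):
            assert fit.coefficients[f"x{j}"] == 0.0
        assert fit.coefficients[f"x{X.shape[1] - 1}"] != 0.0

    def test_objective_not_worse_than_ols_point(self, rng):
        X, y = _random_problem(rng)
        lam = 0.1
        fit = fit_lasso(X, y, lam)
        ols = fit_lasso(X, y, 0.0)
        beta = np.array([fit.coefficients[f"x{j}"] for j in range(X.shape[1])])
        beta_ols = np.array([ols.coefficients[f"x{j}"]
                             for j in range(X.shape[1])])
        assert (_objective(X, y, beta, fit.intercept, lam)
                <= _objective(X, y, beta_ols, ols.intercept, lam) + 1e-10)

    def test_objective_monotone_in_lambda(self, rng):
        X, y = _random_problem(rng)
        values = []
        for lam in (0.0, 0.05, 0.1, 0.5):
            fit = fit_lasso(X, y, lam)
            beta = np.array([fit.coefficients[f"x{j}"]
                             for j in range(X.shape[1])])
            values.append(_objective(X, y, beta, fit.intercept, lam))
        assert all(b >= a - 1e-10 for a, b in zip(values, values[1:]))

    def test_non_finite_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="finite"):
            fit_lasso(X, np.zeros(3), 0.1)

    def test_negative_lambda_rejected(self, rng):
        X, y = _random_problem(rng)
        with pytest.raises(ValueError):
            fit_lasso(X, y, -0.1)

    def test_r2_bounded(self, rng):
        X, y = _random_problem(rng)
        for lam in (0.0, 0.1, 1.0):
            fit = fit_lasso(X, y, lam)
            assert fit.r2 <= 1.0


class TestLassoPath:
    def test_path_above_lambda_max_ends_zero(self, rng):
        X, y = _random_problem(rng)
        lam_max = lambda_max(X, y)
        path = lasso_path(X, y, [0.01 * lam_max, 0.5 * lam_max, 2 * lam_max])
        assert all(v == 0.0 for v in path.fits[-1].coefficients.values())

    def test_singleton_grid_equals_direct_fit(self, rng):
        X, y = _random_problem(rng)
        lam = 0.3 * lambda_max(X, y)
        path = lasso_path(X, y, [lam])
        direct = fit_lasso(X, y, lam)
        assert path.fits[0].coefficients == pytest.approx(direct.coefficients)

    def test_l1_norm_non_increasing(self, rng):
        for _ in range(3):
            X, y = _random_problem(rng, n=60, p=8)
            grid = np.geomspace(1e-3, 1.2 * lambda_max(X, y), 12)
            path = lasso_path(X, y, list(grid))
            norms = [f.l1_norm for f in path.fits]
            assert all(b <= a + 1e-6 for a, b in zip(norms, norms[1:]))

    def test_dominant_feature_survives_longest(self, rng):
        n = 200
        X = rng.normal(size=(n, 5))
        y = 3.0 * X[:, 2] + 0.2 * X[:, 0] + 0.05 * rng.normal(size=n)
        grid = np.geomspace(1e-3, 0.99 * lambda_max(X, y), 20)
        path = lasso_path(X, y, list(grid))
        last_active = None
        for fit in path.fits:
            active = [k for k, v in fit.coefficients.items() if v != 0.0]
            if active:
                last_active = active
        assert last_active == ["x2"]

    def test_decreasing_grid_rejected(self, rng):
        X, y = _random_problem(rng)
        with pytest.raises(ValueError, match="increasing"):
            lasso_path(X, y, [0.5, 0.1])

    def test_default_grid_shape(self, rng):
        X, y = _random_problem(rng)
        grid = default_lambda_grid(X, y)
        assert len(grid) == 16
        assert grid[0] == pytest.approx(1e-3)
        assert grid[-1] == pytest.approx(lambda_max(X, y))


class TestFitLinear:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept, r2, sd = fit_linear(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_independent_data_null_r2(self):
        rng = np.random.default_rng(123)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        _, _, r2, _ = fit_linear(x, y)
        assert r2 < 0.01

    def test_matches_normal_equations(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 7.0])
        A = np.column_stack([np.ones(4), x])
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        slope, intercept, r2, sd = fit_linear(x, y)
        assert intercept == pytest.approx(ref[0], abs=1e-10)
        assert slope == pytest.approx(ref[1], abs=1e-10)
        resid = y - A @ ref
        assert sd == pytest.approx(np.sqrt(resid @ resid / 2), abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1.0, 2.0], [1.0, 2.0])


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 10_000))
def test_kkt_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    X, y = _random_problem(rng, n=25, p=5)
    lam = float(rng.uniform(0.01, 1.5)) * lambda_max(X, y)
    fit = fit_lasso(X, y, lam)
    assert kkt_residual(X, y, fit) <= 1e-6
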