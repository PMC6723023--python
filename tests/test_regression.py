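import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import BLACKBERRY_TAC_COEFFS, blackberry_spec
from pulpcolor.colorimetry import ColorTriplet
from pulpcolor.dataset import FruitDataset
from pulpcolor.exceptions import (
    InsufficientDataError,
    NegativePredictionWarning,
    SingularSystemError,
    UndefinedCorrelationError,
    ValidationError,
)
from pulpcolor.regression import (
    coefficient_t_statistics,
    correlation_matrix,
    filter_by_residuals,
    fit_linear_model,
    fit_with_filtering,
    predict_content,
    refit_filtered,
    solve_normal_equations,
)
from pulpcolor.synthetic import generate_fruit_dataset


def make_dataset(L, a, b, y, fruit="Synthetic", analyte="TAC"):
    frame = pd.DataFrame(
        {
            "sample_id": np.arange(len(y)),
            "replicate": 1,
            "L": L,
            "a": a,
            "b": b,
            "content": y,
        }
    )
    return FruitDataset(fruit, analyte, frame)


class TestNormalEquations:
    def test_univariate_quadratic_layout(self):
        # Classical polynomial normal equations as a special case: exact
        # linear data through (0,2), (1,5), (2,8) gives A=0, B=3, C=2.
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([2.0, 5.0, 8.0])
        design = np.column_stack([x**2, x, np.ones_like(x)])
        coeffs, _ = solve_normal_equations(design, y)
        assert np.allclose(coeffs, [0.0, 3.0, 2.0], atol=1e-10)

    def test_constant_response_with_intercept(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=(10, 3))])
        coeffs, _ = solve_normal_equations(X, np.full(10, 4.2))
        assert np.allclose(coeffs, [4.2, 0, 0, 0], atol=1e-10)

    def test_agrees_with_independent_least_squares_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 200))
            p = int(rng.integers(2, 7))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            ours, _ = solve_normal_equations(X, y)
            oracle = np.linalg.lstsq(X, y, rcond=None)[0]
            assert np.max(np.abs(ours - oracle)) <= 1e-8

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(6), np.arange(6.0), 2 * np.arange(6.0)])
        with pytest.raises(SingularSystemError):
            solve_normal_equations(X, np.arange(6.0))


class TestFitLinearModel:
    def test_exact_recovery_on_noiseless_data(self, rng):
        L = rng.uniform(10, 60, 30)
        a = rng.uniform(-5, 15, 30)
        b = rng.uniform(0, 35, 30)
        y = 10.0 + 1.0 * L - 2.0 * a + 0.5 * b
        fit = fit_linear_model(make_dataset(L, a, b, y))
        assert np.allclose(fit.coefficients, [10.0, 1.0, -2.0, 0.5], atol=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_has_near_zero_r_squared(self, rng):
        n = 5000
        L = rng.uniform(10, 60, n)
        a = rng.uniform(-5, 15, n)
        b = rng.uniform(0, 35, n)
        y = rng.normal(size=n)
        fit = fit_linear_model(make_dataset(L, a, b, y))
        assert fit.r_squared < 0.01

    def test_recovers_published_coefficients_from_noisy_synthetic(self):
        dataset = generate_fruit_dataset(blackberry_spec(noise_sd=50.0, seed=1))
        fit = fit_linear_model(dataset)
        truth = np.asarray(BLACKBERRY_TAC_COEFFS)
        se = np.sqrt(fit.xtx_inverse_diagonal * fit.residual_variance)
        assert np.all(np.abs(fit.coefficients - truth) <= 3 * se)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_linear_model(
                make_dataset(
                    rng.uniform(size=4), rng.uniform(size=4),
                    rng.uniform(size=4), rng.uniform(size=4),
                )
            )

    def test_ols_identities(self, noisy_dataset):
        fit = fit_linear_model(noisy_dataset)
        y = noisy_dataset.response
        # residuals of an intercept model sum to zero
        assert abs(fit.residuals.sum()) <= 1e-8 * np.linalg.norm(y)
        # prediction at the training mean color equals the training mean content
        assert predict_content(
            fit.coefficients, noisy_dataset.mean_color()
        ) == pytest.approx(y.mean(), rel=1e-10)

    def test_r_squared_non_decreasing_with_added_predictor(self, noisy_dataset):
        X = noisy_dataset.design_matrix
        y = noisy_dataset.response

        def r2(design):
            coeffs, _ = solve_normal_equations(design, y)
            resid = y - design @ coeffs
            return 1 - resid @ resid / np.sum((y - y.mean()) ** 2)

        assert r2(X[:, :3]) <= r2(X) + 1e-12


class TestCoefficientInference:
    def test_matches_statsmodels_oracle_on_small_instance(self, rng):
        L = rng.uniform(10, 60, 6)
        a = rng.uniform(-5, 15, 6)
        b = rng.uniform(0, 35, 6)
        y = 5 + 0.5 * L - a + 0.1 * b + rng.normal(size=6)
        dataset = make_dataset(L, a, b, y)
        fit = fit_linear_model(dataset)
        t, p = coefficient_t_statistics(fit)
        oracle = sm.OLS(y, dataset.design_matrix).fit()
        assert np.max(np.abs(t - oracle.tvalues)) <= 1e-8
        assert np.max(np.abs(p - oracle.pvalues)) <= 1e-8

    def test_zero_residual_variance_flags_infinite_t(self):
        from pulpcolor.regression import RegressionFit

        fit = RegressionFit(
            fruit_label="Synthetic",
            analyte="TAC",
            coefficients=np.array([2.0, 0.0, -1.0, 0.0]),
            residuals=np.zeros(10),
            residual_variance=0.0,
            xtx_inverse_diagonal=np.ones(4),
            t_statistics=np.zeros(4),
            r_squared=1.0,
            n_used=10,
            dof=6,
        )
        t, p = coefficient_t_statistics(fit)
        # zero coefficients get t = 0; the rest are flagged infinite, p = 0
        assert np.array_equal(np.isinf(t), [True, False, True, False])
        assert t[1] == t[3] == 0.0
        assert np.all(p[np.isinf(t)] == 0.0)


class TestCorrelationMatrix:
    def test_exact_linear_dependence(self, rng):
        L = rng.uniform(10, 60, 20)
        dataset = make_dataset(L, rng.normal(size=20), rng.normal(size=20), 2 * L)
        corr = correlation_matrix(dataset)
        assert corr.loc["content", "L"] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_matches_brute_force_pairwise_formula(self, rng):
        columns = rng.normal(size=(6, 4))
        dataset = make_dataset(
            np.abs(columns[:, 1]) * 10, columns[:, 2], columns[:, 3], columns[:, 0]
        )
        corr = correlation_matrix(dataset).to_numpy()
        data = np.column_stack(
            [dataset.response, dataset.frame["L"], dataset.frame["a"], dataset.frame["b"]]
        )
        for i in range(4):
            for j in range(4):
                x, y = data[:, i], data[:, j]
                brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                    np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
                )
                assert corr[i, j] == pytest.approx(brute, abs=1e-12)

    def test_independent_noise_has_small_correlation(self, rng):
        n = 10_000
        dataset = make_dataset(
            rng.uniform(0, 100, n),
            rng.normal(size=n),
            rng.normal(size=n),
            rng.normal(size=n),
        )
        corr = correlation_matrix(dataset)
        assert np.abs(corr.loc["content", ["L", "a", "b"]]).max() < 0.05

    def test_constant_column_names_the_offender(self, rng):
        dataset = make_dataset(
            np.full(10, 50.0), rng.normal(size=10), rng.normal(size=10),
            rng.normal(size=10),
        )
        with pytest.raises(UndefinedCorrelationError, match="'L'"):
            correlation_matrix(dataset)


class TestResidualFiltering:
    def test_zero_residuals_keep_everything(self, noiseless_dataset):
        fit = fit_linear_model(noiseless_dataset)
        report = filter_by_residuals(fit, noiseless_dataset)
        assert len(report.kept_indices) == 45
        assert len(report.dropped_indices) == 0

    def test_huge_threshold_keeps_everything(self, noisy_dataset):
        fit = fit_linear_model(noisy_dataset)
        report = filter_by_residuals(fit, noisy_dataset, k=1e6)
        assert len(report.dropped_indices) == 0

    def test_injected_gross_outlier_is_dropped(self, noisy_dataset):
        frame = noisy_dataset.frame.copy()
        fit0 = fit_linear_model(noisy_dataset)
        sigma0 = np.sqrt(fit0.residual_variance)
        frame.loc[7, "content"] += 10 * sigma0
        corrupted = FruitDataset("Blackberry", "TAC", frame)
        fit = fit_linear_model(corrupted)
        report = filter_by_residuals(fit, corrupted, k=2.0)
        assert list(report.dropped_indices) == [7]

    def test_invalid_multiplier_rejected(self, noisy_dataset):
        fit = fit_linear_model(noisy_dataset)
        with pytest.raises(ValidationError):
            filter_by_residuals(fit, noisy_dataset, k=0.0)

    def test_refit_without_drops_is_identical(self, noiseless_dataset):
        fit = fit_linear_model(noiseless_dataset)
        report = filter_by_residuals(fit, noiseless_dataset)
        refit = refit_filtered(noiseless_dataset, report)
        assert np.allclose(refit.coefficients, fit.coefficients, atol=1e-12)

    def test_refit_moves_coefficients_toward_truth(self):
        # Planted 10-sigma outliers bias the initial fit; after filtering,
        # the refit is closer to truth on average (and in most instances --
        # alternating-sign shifts can partially cancel in any one sample).
        truth = np.asarray(BLACKBERRY_TAC_COEFFS)
        initial_dist, refit_dist = [], []
        for seed in range(100):
            dataset = generate_fruit_dataset(
                blackberry_spec(outlier_fraction=0.08, outlier_shift=10.0, seed=seed)
            )
            initial = fit_linear_model(dataset)
            report = filter_by_residuals(initial, dataset, k=2.0)
            refit = refit_filtered(dataset, report)
            assert refit.provenance["filter_report"] is report
            initial_dist.append(np.linalg.norm(initial.coefficients - truth))
            refit_dist.append(np.linalg.norm(refit.coefficients - truth))
        improved = np.sum(np.array(refit_dist) < np.array(initial_dist))
        assert np.mean(refit_dist) < np.mean(initial_dist)
        assert improved >= 70

    def test_second_pass_drops_few_clean_rows(self):
        # With Gaussian noise and k = 2 the first pass trims the ~5% tail;
        # a refit barely changes sigma, so a second pass removes little.
        second_pass_fractions = []
        for seed in range(200):
            dataset = generate_fruit_dataset(blackberry_spec(seed=seed))
            _, reports = fit_with_filtering(dataset, k=2.0, passes=2)
            if len(reports) == 2:
                n_before = len(reports[1].kept_indices) + len(reports[1].dropped_indices)
                second_pass_fractions.append(
                    len(reports[1].dropped_indices) / n_before
                )
            else:
                second_pass_fractions.append(0.0)
        assert np.mean(second_pass_fractions) <= 0.07


class TestPredictContent:
    def test_intercept_only(self):
        assert predict_content((3.0, 0, 0, 0), ColorTriplet(42.0, 1.0, -1.0)) == 3.0

    def test_negative_prediction_warns_but_is_not_clamped(self):
        with pytest.warns(NegativePredictionWarning):
            value = predict_content((-10.0, 0, 0, 0), ColorTriplet(5.0, 0.0, 0.0))
        assert value == -10.0

    def test_wrong_coefficient_count_rejected(self):
        with pytest.raises(ValidationError):
            predict_content((1.0, 2.0), ColorTriplet(5.0, 0.0, 0.0))
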