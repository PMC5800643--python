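"""Linearized CIs against closed forms; Monte-Carlo band behaviour."""

import numpy as np
import pytest
from scipy import stats

from tauphos.calibration import FitResult
from tauphos.uncertainty import linearized_ci, monte_carlo_band


def linear_regression_fit(seed=0, n=40, theta=(1.5, -0.7), sigma=0.4):
    """Least-squares fit of y = X·theta with known closed-form CIs."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 1, n)
    X = np.column_stack([x, np.ones(n)])
    y = X @ np.asarray(theta) + rng.normal(0, sigma, n)
    hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = X @ hat - y
    return FitResult(param_names=["slope", "intercept"], x=hat,
                     estimates=dict(zip(["slope", "intercept"], hat)),
                     objective=float(resid @ resid), grouping=None,
                     residuals=resid, jacobian=X,
                     bounds=(np.full(2, -np.inf), np.full(2, np.inf))), X, y


class TestLinearizedCI:
    def test_matches_closed_form_linear_regression(self):
        fit, X, y = linear_regression_fit()
        report = linearized_ci(fit)
        n, p = X.shape
        s2 = fit.objective / (n - p)
        cov = s2 * np.linalg.inv(X.T @ X)
        tq = stats.t.ppf(0.975, n - p)
        for j, name in enumerate(fit.param_names):
            lo, hi = report.intervals[name]
            assert lo == pytest.approx(fit.x[j] - tq * np.sqrt(cov[j, j]),
                                       abs=1e-6)
            assert hi == pytest.approx(fit.x[j] + tq * np.sqrt(cov[j, j]),
                                       abs=1e-6)
        assert report.all_identifiable

    def test_intervals_bracket_estimates(self):
        fit, *_ = linear_regression_fit(seed=3)
        report = linearized_ci(fit)
        for name in fit.param_names:
            lo, hi = report.intervals[name]
            assert lo <= report.estimates[name] <= hi

    def test_redundant_parameter_flagged_not_pseudo_inverted(self):
        # theta1 + theta2 identifiable only in sum → rank-deficient Jacobian
        rng = np.random.default_rng(1)
        x = np.linspace(0, 1, 30)
        X = np.column_stack([x, x])  # identical columns
        y = 2 * x + rng.normal(0, 0.1, 30)
        fit = FitResult(param_names=["theta1", "theta2"], x=np.array([1.0, 1.0]),
                        estimates={"theta1": 1.0, "theta2": 1.0},
                        objective=0.1, grouping=None, residuals=X @ [1, 1] - y,
                        jacobian=X, bounds=(np.full(2, -np.inf),
                                            np.full(2, np.inf)))
        report = linearized_ci(fit)
        assert set(report.non_identifiable) == {"theta1", "theta2"}
        assert report.intervals is None

    def test_ci_width_shrinks_with_replication(self):
        # homoscedastic replication: width ~ 1/sqrt(n)
        widths = {}
        for n in (40, 160):
            fit, *_ = linear_regression_fit(seed=5, n=n)
            report = linearized_ci(fit)
            lo, hi = report.intervals["slope"]
            widths[n] = hi - lo
        ratio = widths[40] / widths[160]
        assert 1.5 < ratio < 2.8  # ideal 2.0, noise on sigma-hat allowed

    def test_synthetic_tau_fit_reports_all_identifiable(self, compact_fit):
        _model, _bundle, fit = compact_fit
        report = linearized_ci(fit)
        assert report.all_identifiable
        assert fit.ci95 is not None and fit.covariance is not None


class TestMonteCarloBand:
    def predictor(self, X):
        return lambda theta: X @ np.asarray(theta)

    def test_zero_covariance_collapses_to_central_trajectory(self):
        fit, X, _ = linear_regression_fit()
        fit.covariance = np.zeros((2, 2))
        rep = monte_carlo_band(fit, self.predictor(X), X[:, 0], n_draws=50)
        assert np.allclose(rep.band_lower, rep.band_central)
        assert np.allclose(rep.band_upper, rep.band_central)

    def test_deterministic_given_seed(self):
        fit, X, _ = linear_regression_fit()
        linearized_attach(fit)
        r1 = monte_carlo_band(fit, self.predictor(X), X[:, 0], 200, seed=42)
        r2 = monte_carlo_band(fit, self.predictor(X), X[:, 0], 200, seed=42)
        assert np.array_equal(r1.band_lower, r2.band_lower)
        r3 = monte_carlo_band(fit, self.predictor(X), X[:, 0], 200, seed=43)
        assert not np.array_equal(r1.band_lower, r3.band_lower)

    def test_band_envelopes_central_and_matches_linear_theory(self):
        fit, X, _ = linear_regression_fit(seed=7, n=60)
        linearized_attach(fit)
        rep = monte_carlo_band(fit, self.predictor(X), X[:, 0],
                               n_draws=2000, seed=0)
        assert np.all(rep.band_lower <= rep.band_central + 1e-12)
        assert np.all(rep.band_upper >= rep.band_central - 1e-12)
        # for a linear observable the MC band converges to the normal band
        sd = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.covariance, X))
        expected_half = 1.96 * sd
        mc_half = 0.5 * (rep.band_upper - rep.band_lower)
        assert np.allclose(mc_half, expected_half, rtol=0.15)

    def test_coverage_of_true_curve_near_nominal(self):
        # repeated noisy regressions: the 95% band covers the true line
        # at roughly nominal pointwise rate
        covered, total = 0, 0
        truth = np.asarray([1.5, -0.7])
        for seed in range(30):
            fit, X, _ = linear_regression_fit(seed=seed, n=40)
            linearized_attach(fit)
            rep = monte_carlo_band(fit, self.predictor(X), X[:, 0],
                                   n_draws=300, seed=seed)
            y_true = X @ truth
            covered += int(np.sum((rep.band_lower <= y_true)
                                  & (y_true <= rep.band_upper)))
            total += len(y_true)
        assert 0.88 <= covered / total <= 1.0


def linearized_attach(fit):
    from tauphos.uncertainty import attach_linearized_ci
    attach_linearized_ci(fit)
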