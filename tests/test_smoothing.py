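"""Penalized spline smoothing: basis, penalty, GCV, noise estimation."""

import numpy as np
import pytest

from gmgts import (
    CellMeasurements,
    auto_knots,
    build_basis,
    estimate_noise,
    fit_penalized,
    select_lambda,
    simulate_individual,
    smooth_cell,
)
from gmgts.smoothing import NoiseEstimate


@pytest.fixture(scope="module")
def basis21():
    t = np.linspace(0.0, 20.0, 21)
    return t, build_basis(np.linspace(0.0, 20.0, 8), t)


class TestBasis:
    def test_partition_of_unity(self, basis21):
        _, basis = basis21
        np.testing.assert_allclose(basis.B.sum(axis=1), 1.0, atol=1e-12)

    def test_derivative_of_constant_vanishes(self, basis21):
        _, basis = basis21
        np.testing.assert_allclose(basis.Bdot.sum(axis=1), 0.0, atol=1e-10)

    def test_derivative_matrix_matches_finite_differences(self, basis21):
        _, basis = basis21
        eps = 1e-6
        mid = np.linspace(0.5, 19.5, 31)
        fd = (basis.design(mid + eps) - basis.design(mid - eps)) / (2 * eps)
        np.testing.assert_allclose(basis.design(mid, deriv=1), fd, atol=1e-5)

    def test_penalty_annihilates_straight_lines(self, basis21):
        t, basis = basis21
        fit = fit_penalized(2.0 + 3.0 * t, basis, lam=0.0)
        q = fit.coef @ basis.penalty @ fit.coef
        assert abs(q) < 1e-10
        np.testing.assert_allclose(fit.fitted, 2.0 + 3.0 * t, atol=1e-9)

    def test_too_many_knots_rejected(self):
        t = np.linspace(0, 1, 6)
        with pytest.raises(ValueError, match="fewer knots"):
            build_basis(np.linspace(0, 1, 10), t)


class TestFitPenalized:
    def test_unpenalized_rich_basis_interpolates_cubic(self):
        t = np.linspace(0.0, 10.0, 11)
        basis = build_basis(np.linspace(0.0, 10.0, 8), t)
        y = 1.0 - 2 * t + 0.3 * t**2 - 0.01 * t**3
        fit = fit_penalized(y, basis, lam=0.0)
        np.testing.assert_allclose(fit.fitted, y, atol=1e-10)

    def test_infinite_penalty_limit_is_weighted_line(self, rng):
        t = np.linspace(0.0, 20.0, 21)
        basis = build_basis(np.linspace(0.0, 20.0, 8), t)
        y = np.sin(t / 4) + 0.1 * rng.standard_normal(21)
        w = rng.uniform(0.5, 2.0, 21)
        fit = fit_penalized(y, basis, weights=w, lam=1e12)
        coefs = np.polyfit(t, y, 1, w=np.sqrt(w))
        np.testing.assert_allclose(fit.fitted, np.polyval(coefs, t), atol=1e-5)

    def test_coef_cov_matches_pseudoinverse_oracle(self, basis21, rng):
        """With unit weights, lam=0 and Sigma_y = I: cov = (B'B)^-1."""
        t, basis = basis21
        y = rng.standard_normal(21)
        fit = fit_penalized(y, basis, lam=0.0, y_var=np.ones(21))
        oracle = np.linalg.pinv(basis.B.T @ basis.B)
        np.testing.assert_allclose(fit.coef_cov, oracle, atol=1e-8)

    def test_smoother_is_linear_in_data(self, basis21, rng):
        t, basis = basis21
        w = rng.uniform(0.5, 2.0, 21)
        y1, y2 = rng.standard_normal((2, 21))
        f = lambda y: fit_penalized(y, basis, weights=w, lam=3.7).fitted
        np.testing.assert_allclose(f(2 * y1 - 3 * y2), 2 * f(y1) - 3 * f(y2), atol=1e-9)

    def test_nonpositive_weights_rejected(self, basis21, rng):
        t, basis = basis21
        with pytest.raises(ValueError, match="positive"):
            fit_penalized(np.zeros(21), basis, weights=np.zeros(21))


class TestSelectLambda:
    def test_pure_noise_selects_heavy_penalty(self):
        rng = np.random.default_rng(123)
        t = np.linspace(0.0, 20.0, 60)
        basis = build_basis(np.linspace(0.0, 20.0, 8), t)
        picks = [select_lambda(5.0 + rng.standard_normal(60), basis) for _ in range(7)]
        assert np.median(picks) >= 1e2  # top decade of the 1e-6..1e3 grid

    def test_smooth_signal_selects_light_penalty(self, basis21):
        t, basis = basis21
        y = np.exp(-0.2 * t) + 0.05 * t
        assert select_lambda(y, basis) < np.sqrt(1e-6 * 1e3)  # bottom half

    def test_deterministic(self, basis21, rng):
        t, basis = basis21
        y = np.sin(t / 3) + 0.1 * rng.standard_normal(21)
        w = rng.uniform(0.5, 2.0, 21)
        assert select_lambda(y, basis, w) == select_lambda(y, basis, w)

    def test_fast_scan_matches_bruteforce(self, basis21, rng):
        t, basis = basis21
        y = np.sin(t / 3) + 0.1 * rng.standard_normal(21)
        w = rng.uniform(0.5, 2.0, 21)
        grid = np.logspace(-6, 3, 40)
        best, score = None, np.inf
        for lam in grid:
            fit = fit_penalized(y, basis, w, lam)
            rss = float(np.sum(w * (y - fit.fitted) ** 2))
            s = 21 * rss / (21 - fit.edf) ** 2
            if s < score:
                best, score = lam, s
        assert select_lambda(y, basis, w) == pytest.approx(best)


class TestEstimateNoise:
    def test_noiseless_data_gives_zero(self, basis21):
        t, basis = basis21
        y = np.exp(-0.1 * t)
        fit = fit_penalized(y, basis, lam=1e-6)
        est = estimate_noise(y, fit)
        assert est.sigma_hat < 1e-5 and est.tau_hat < 1e-5

    def test_multiplicative_recovery_monte_carlo(self):
        """Constant signal x*=10, tau=0.05: mean tau_hat within 10%."""
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 10.0, 200)
        basis = build_basis(np.linspace(0.0, 10.0, 8), t)
        taus = []
        for _ in range(200):
            y = 10.0 * (1.0 + 0.05 * rng.standard_normal(200))
            lam = 10.0
            fit = fit_penalized(y, basis, lam=lam)
            taus.append(estimate_noise(y, fit).tau_hat)
        assert abs(np.mean(taus) - 0.05) < 0.005

    def test_additive_only_noise(self):
        """tau = 0: sigma recovered, tau concentrates near zero."""
        rng = np.random.default_rng(8)
        t = np.linspace(0.0, 10.0, 200)
        basis = build_basis(np.linspace(0.0, 10.0, 8), t)
        sigmas, taus = [], []
        for _ in range(100):
            y = 0.05 * t + 0.3 * rng.standard_normal(200)
            fit = fit_penalized(y, basis, lam=10.0)
            est = estimate_noise(y, fit)
            sigmas.append(est.sigma_hat)
            taus.append(est.tau_hat)
        assert abs(np.mean(sigmas) - 0.3) < 0.03
        assert np.median(taus) < 0.1


class TestAutoKnots:
    def test_monotone_series_needs_few_knots(self):
        t = np.linspace(0.0, 20.0, 41)
        knots = auto_knots(np.exp(0.1 * t), t)
        assert len(knots) - 2 <= 3

    def test_oscillation_knots_bracket_extrema(self):
        t = np.linspace(0.0, 2 * np.pi, 60)
        knots = auto_knots(np.sin(t), t)
        interior = knots[1:-1]
        dt = t[1] - t[0]
        # one full period: extrema at pi/2 and 3pi/2
        for ext in (np.pi / 2, 3 * np.pi / 2):
            assert np.min(np.abs(interior - ext)) < 2 * dt

    def test_deterministic(self, rng):
        t = np.linspace(0, 10, 30)
        y = np.sin(t) + 0.1 * rng.standard_normal(30)
        np.testing.assert_array_equal(auto_knots(y, t), auto_knots(y, t))


class TestSmoothCell:
    def test_noiseless_trajectory_recovered(self, lv_model, lv_traj_dense):
        beta, tgrid, traj = lv_traj_dense
        sm = smooth_cell(CellMeasurements("c", tgrid, traj))
        rel = np.abs(sm.xhat - traj).max(axis=0) / (traj.max(axis=0) - traj.min(axis=0))
        assert rel.max() < 0.01

    def test_noiseless_gradients_recovered(self, lv_model, lv_traj_dense):
        beta, tgrid, traj = lv_traj_dense
        sm = smooth_cell(CellMeasurements("c", tgrid, traj))
        xdot = np.array([lv_model.rhs(traj[j], beta) for j in range(len(tgrid))])
        interior = slice(5, -5)
        err = np.abs(sm.xdot_hat - xdot)[interior].max(axis=0)
        rng_d = xdot.max(axis=0) - xdot.min(axis=0) + 1e-12
        assert (err / rng_d).max() < 0.05

    def test_reweighting_fixed_point(self, lv_cell_noisy):
        _, _, cell = lv_cell_noisy
        sm = smooth_cell(cell)
        again = smooth_cell(
            cell,
            knots=[f.basis.knots for f in sm.fits],
            lam=[f.lam for f in sm.fits],
            noise_override=sm.noise,
        )
        for f1, f2 in zip(sm.fits, again.fits):
            scale = np.abs(f1.fitted).max()
            np.testing.assert_allclose(f1.fitted, f2.fitted, atol=5e-3 * scale)

    def test_derivative_consistent_with_value_differences(self, lv_cell_noisy):
        _, _, cell = lv_cell_noisy
        sm = smooth_cell(cell)
        tfine = np.linspace(cell.t[0], cell.t[-1], 2001)
        dt = tfine[1] - tfine[0]
        for f in sm.fits[:4]:
            vals = f(tfine)
            derivs = f(tfine, deriv=1)
            fd = np.gradient(vals, dt)
            scale = np.abs(derivs).max() + 1e-12
            assert np.abs(derivs[5:-5] - fd[5:-5]).max() / scale < 1e-3

    def test_coef_cov_monte_carlo(self):
        """Empirical coefficient covariance over noise replicates matches
        the reported one within 25% Frobenius error."""
        rng = np.random.default_rng(11)
        t = np.linspace(0.0, 10.0, 41)
        x = 5.0 + np.sin(t / 2)
        tau = 0.05
        basis = build_basis(np.linspace(0.0, 10.0, 9), t)
        var = (tau * x) ** 2
        lam = 1.0
        coefs = []
        for _ in range(500):
            y = x + np.sqrt(var) * rng.standard_normal(len(t))
            coefs.append(fit_penalized(y, basis, 1.0 / var, lam, y_var=var).coef)
        emp = np.cov(np.array(coefs).T)
        rep = fit_penalized(x, basis, 1.0 / var, lam, y_var=var).coef_cov
        rel = np.linalg.norm(emp - rep) / np.linalg.norm(rep)
        assert rel < 0.25

    def test_noise_variance_floor(self):
        est = NoiseEstimate(sigma_hat=0.0, tau_hat=0.1)
        v = est.variance(np.array([0.0, 1.0]))
        assert v[0] == 0.0 and v[1] == pytest.approx(0.01)
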