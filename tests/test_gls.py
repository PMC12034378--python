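"""Gradient matching with full state information: assembly, GLS, FGLS."""

import numpy as np
import pytest

from gmgts import (
    CellMeasurements,
    GLSSystem,
    LinearODEModel,
    assemble_system,
    fgls_fit,
    gls_solve,
    make_lotka_volterra,
    residual_covariance,
    simulate_individual,
    smooth_cell,
)
from gmgts.gls import propagation_matrix, sandwich_covariance


@pytest.fixture(scope="module")
def lv_fits(lv_cell_noisy_module):
    model, meas, cell = lv_cell_noisy_module
    return model, smooth_cell(cell).fits


@pytest.fixture(scope="module")
def lv_cell_noisy_module():
    from gmgts import generate_scenario

    ds = generate_scenario("lotka_volterra_full", seed=101, overrides={"N": 1})
    return ds.model, ds.measurement, ds.cells[0]


class TestAssemble:
    def test_dimensions(self, lv_fits):
        """16 states x 21 time points, 4 tied parameters: 336 x 4 design."""
        model, fits = lv_fits
        sys = assemble_system(model, fits)
        assert sys.Gmat.shape == (336, 4)
        assert sys.dvec.shape == (336,)
        np.testing.assert_array_equal(sys.V, np.eye(336))

    def test_design_entries_follow_ring_structure(self, lv_fits):
        model, fits = lv_fits
        sys = assemble_system(model, fits)
        xhat = np.column_stack([f.fitted for f in fits])
        j, n = 7, 4  # arbitrary time point; state 5 ties to column (n mod 4)
        row = sys.Gmat[j * 16 + n]
        col = n % 4
        np.testing.assert_allclose(row[col], -xhat[j, n] * xhat[j, n + 1])
        assert np.all(row[np.arange(4) != col] == 0)

    def test_offset_is_growth_term(self, lv_fits):
        model, fits = lv_fits
        sys = assemble_system(model, fits)
        xhat = np.column_stack([f.fitted for f in fits])
        xdot = np.column_stack([f.fitted_deriv for f in fits])
        r = np.arange(1, 17) / 80.0
        j = 3
        np.testing.assert_allclose(sys.dvec[j * 16 : (j + 1) * 16], xdot[j] - r * xhat[j])

    def test_missing_fit_rejected(self, lv_fits):
        model, fits = lv_fits
        with pytest.raises(ValueError, match="one spline fit per state"):
            assemble_system(model, fits[:-1])


class TestGLSSolve:
    def test_identity_v_equals_ols_oracle(self, rng):
        G = rng.standard_normal((30, 3))
        d = rng.standard_normal(30)
        beta = gls_solve(GLSSystem(G, d, np.eye(30)))
        oracle = np.linalg.solve(G.T @ G, G.T @ d)
        np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_scalar_closed_form(self, rng):
        g = rng.standard_normal(20)
        d = rng.standard_normal(20)
        v = rng.uniform(0.5, 2.0, 20)
        beta = gls_solve(GLSSystem(g[:, None], d, np.diag(v)))
        np.testing.assert_allclose(beta[0], np.sum(g * d / v) / np.sum(g**2 / v))

    def test_exact_data_recovered_under_any_v(self, rng):
        G = rng.standard_normal((25, 4))
        beta0 = rng.standard_normal(4)
        A = rng.standard_normal((25, 25))
        V = A @ A.T + 25 * np.eye(25)
        beta = gls_solve(GLSSystem(G, G @ beta0, V))
        np.testing.assert_allclose(beta, beta0, atol=1e-8)

    def test_collinear_columns_reported(self, rng):
        g = rng.standard_normal(20)
        G = np.column_stack([g, g])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            gls_solve(GLSSystem(G, rng.standard_normal(20), np.eye(20)))

    def test_gls_minimizes_quadratic_objective(self, rng):
        """Cross-check against a derivative-free minimizer on a small case."""
        from scipy.optimize import minimize

        G = rng.standard_normal((12, 2))
        d = rng.standard_normal(12)
        A = rng.standard_normal((12, 12))
        V = A @ A.T + 12 * np.eye(12)
        Vinv = np.linalg.inv(V)
        obj = lambda b: (d - G @ b) @ Vinv @ (d - G @ b)
        direct = minimize(obj, np.zeros(2), method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-14})
        np.testing.assert_allclose(gls_solve(GLSSystem(G, d, V)), direct.x, atol=1e-5)


def _state_independent_model():
    """2-state system with rhs independent of x: xdot = diag(beta) 1 + c."""
    g = lambda x: np.array([[1.0, 0.0], [0.0, 1.0]])
    h = lambda x: np.array([0.5, -0.2])
    return LinearODEModel(
        K=2, P=2, state_names=["a", "b"], param_names=["p", "q"],
        x0=np.zeros(2), g=g, h=h, name="flat",
    )


class TestResidualCovariance:
    def test_state_independent_rhs_uses_only_gradient_errors(self):
        """J = 0: V reduces to Bdot Sigma_c Bdot' (plus the ridge)."""
        from gmgts import build_basis, fit_penalized

        model = _state_independent_model()
        t = np.linspace(0, 10, 15)
        basis = build_basis(np.linspace(0, 10, 6), t)
        rng = np.random.default_rng(0)
        fits = [fit_penalized(rng.standard_normal(15), basis, lam=0.1) for _ in range(2)]
        V = residual_covariance(model, fits, np.zeros(2))
        nb = basis.n_basis
        expect = np.zeros((30, 30))
        for k in range(2):
            Mk = np.zeros((30, nb))
            for j in range(15):
                Mk[j * 2 + k] = basis.Bdot[j]
            expect += Mk @ fits[k].coef_cov @ Mk.T
        ridge = 1e-8 * np.trace(expect) / 30
        expect[np.diag_indices(30)] += ridge
        np.testing.assert_allclose(V, expect, atol=1e-10)

    def test_zero_coef_cov_leaves_ridge(self):
        from gmgts import build_basis, fit_penalized

        model = _state_independent_model()
        t = np.linspace(0, 10, 15)
        basis = build_basis(np.linspace(0, 10, 6), t)
        fits = [fit_penalized(np.sin(t), basis, lam=0.1) for _ in range(2)]
        for f in fits:
            f.coef_cov = np.zeros_like(f.coef_cov)
        V = residual_covariance(model, fits, np.zeros(2))
        assert np.abs(V - np.diag(np.diag(V))).max() == 0.0

    def test_monte_carlo_validation(self):
        """Empirical Cov(Delta) over noise replicates of one cell matches the
        delta-method V within 30% relative Frobenius error."""
        from gmgts import (
            MeasurementModel,
            build_basis,
            fit_penalized,
            observe,
        )

        model = make_lotka_volterra(2)
        beta_t = np.full(2, 0.02)
        t = np.linspace(0, 20, 21)
        traj = simulate_individual(model, beta_t, t)
        meas = MeasurementModel.identity(16, sigma=0.0, tau=0.05)
        basis = build_basis(np.linspace(0, 20, 9), t)
        var = np.maximum((0.05 * traj) ** 2, 1e-10)
        lam = 1.0
        rng = np.random.default_rng(4)

        def fits_for(y):
            return [
                fit_penalized(y[:, k], basis, 1.0 / var[:, k], lam, y_var=var[:, k])
                for k in range(16)
            ]

        deltas = []
        for _ in range(400):
            y = observe(traj, meas, rng)
            fits = fit_for = fits_for(y)
            xhat = np.column_stack([f.fitted for f in fits])
            xdot = np.column_stack([f.fitted_deriv for f in fits])
            delta = np.empty(21 * 16)
            for j in range(21):
                delta[j * 16 : (j + 1) * 16] = (
                    xdot[j] - model.gmat(xhat[j]) @ beta_t - model.hvec(xhat[j])
                )
            deltas.append(delta)
        emp = np.cov(np.array(deltas).T)
        fits0 = fits_for(traj @ meas.Q.T)
        V = residual_covariance(model, fits0, beta_t)
        rel = np.linalg.norm(emp - V) / np.linalg.norm(V)
        assert rel < 0.30


class TestFGLS:
    def test_noiseless_dense_recovery(self, lv_model, lv_traj_dense):
        beta, tgrid, traj = lv_traj_dense
        sm = smooth_cell(CellMeasurements("c", tgrid, traj))
        est = fgls_fit(lv_model, sm.fits)
        assert np.linalg.norm(est.beta_hat - beta) / np.linalg.norm(beta) < 0.01
        assert est.converged

    def test_first_iterate_is_ols(self, lv_fits):
        model, fits = lv_fits
        est = fgls_fit(model, fits)
        sys = assemble_system(model, fits)
        ols = gls_solve(sys)
        np.testing.assert_allclose(est.history[0], ols, atol=1e-12)

    def test_iterates_settle(self, lv_fits):
        """Relative step sizes decrease towards convergence."""
        model, fits = lv_fits
        est = fgls_fit(model, fits, tol=1e-10, max_iter=8)
        hist = np.array(est.history)
        steps = np.linalg.norm(np.diff(hist, axis=0), axis=1)
        assert steps[-1] <= steps[1] + 1e-12

    def test_covariance_is_psd_and_sized(self, lv_fits):
        model, fits = lv_fits
        est = fgls_fit(model, fits)
        w = np.linalg.eigvalsh(est.C)
        assert w.min() >= -1e-12 * w.max()
        assert est.C.shape == (4, 4)

    def test_sandwich_reduces_to_gls_covariance(self, rng):
        """When the weights equal the inverse of V the sandwich collapses
        to (G' V^-1 G)^-1."""
        G = rng.standard_normal((20, 3))
        A = rng.standard_normal((20, 20))
        V = A @ A.T + 20 * np.eye(20)
        W = 1.0 / np.diag(V)
        # full-weight case
        Vd = np.diag(np.diag(V))
        C = sandwich_covariance(G, 1.0 / np.diag(Vd), Vd)
        np.testing.assert_allclose(C, np.linalg.inv(G.T @ np.linalg.inv(Vd) @ G), atol=1e-10)

    def test_interval_coverage_linear_gaussian(self, rng):
        """With V exact and the model linear, 95% marginal intervals cover
        the truth for 88-99% of replicates."""
        G = rng.standard_normal((40, 3))
        A = rng.standard_normal((40, 40)) * 0.2
        V = A @ A.T + np.eye(40)
        L = np.linalg.cholesky(V)
        beta_t = np.array([1.0, -0.5, 0.25])
        C = np.linalg.inv(G.T @ np.linalg.solve(V, G))
        half = 1.96 * np.sqrt(np.diag(C))
        cover = np.zeros(3)
        n_rep = 300
        for _ in range(n_rep):
            d = G @ beta_t + L @ rng.standard_normal(40)
            bh = gls_solve(GLSSystem(G, d, V))
            cover += np.abs(bh - beta_t) < half
        frac = cover / n_rep
        assert np.all(frac >= 0.88) and np.all(frac <= 0.99)

    def test_unit_rescaling_equivariance(self):
        """Measuring LV abundances in different units rescales the
        interaction rates inversely (k has units 1/(x time))."""
        from gmgts import build_basis, fit_penalized

        model = make_lotka_volterra(4)
        beta = np.full(4, 0.02)
        t = np.linspace(0, 20, 201)
        traj = simulate_individual(model, beta, t)
        c = 3.0

        def estimate(scaled):
            sm = smooth_cell(CellMeasurements("c", t, scaled))
            sys_ = assemble_system(model, sm.fits)
            return gls_solve(sys_)

        b1 = estimate(traj)
        b2 = estimate(c * traj)
        np.testing.assert_allclose(b2, b1 / c, rtol=1e-3)

    def test_propagation_matrix_shape(self, lv_fits):
        model, fits = lv_fits
        M = propagation_matrix(model, fits, np.full(4, 0.02))
        nb = sum(f.basis.n_basis for f in fits)
        assert M.shape == (336, nb)
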