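"""Stage I for partially observed systems.

When some states are unmeasured, gradient matching alternates with
hidden-state reconstruction: the ODE system and its forward sensitivities
are integrated at the current parameter estimate, the hidden states are
treated as (first-order) deterministic functions of the parameters, and the
gradient-matching regression is re-solved on the observed rows with the
hidden dependence folded into the design.  The loop is a damped fixed-point
iteration; uncertainty propagates from the smoothed data through both the
regression residuals and the reconstructed hidden states.

Only the observed rows of the stacked regression carry information: a hidden
row's response and design shift identically under a first-order change of
beta (the integrated gradient *is* the model rate at the current estimate),
so including hidden rows merely anchors the estimate to its previous value —
measurably biasing the fixed point when most states are hidden.  Folding the
sensitivity of the hidden states into the observed-row design instead yields
a Gauss-Newton-type update that converges in a handful of integrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .gls import (
    GLSSystem,
    IndividualEstimate,
    gls_solve,
    sandwich_covariance,
)
from .models import IntegrationError, LinearODEModel, MeasurementModel
from .smoothing import CellSmoothing

__all__ = [
    "HiddenStateEstimate",
    "default_initial_guess",
    "integrate_hidden",
    "propagate_hidden_uncertainty",
    "partial_residual_covariance",
    "stage1_partial",
]

_RIDGE_SCALE = 1e-8


@dataclass
class HiddenStateEstimate:
    """Integrated trajectory, gradients, and parameter sensitivities.

    ``x`` is the full (T, K) solution at ``beta``; ``xdot`` its exact time
    derivative (the rhs along the solution); ``S`` the (T, K, P) forward
    sensitivity dx(t)/dbeta.
    """

    x: np.ndarray
    xdot: np.ndarray
    S: np.ndarray
    beta: np.ndarray

    def hidden(self, hidden_idx: np.ndarray):
        return self.x[:, hidden_idx], self.xdot[:, hidden_idx], self.S[:, hidden_idx, :]


def _row_depends_on_hidden(
    model: LinearODEModel, hidden_idx: np.ndarray, n_probe: int = 5, seed: int = 0
) -> np.ndarray:
    """Which rhs rows (g row or h entry) involve any hidden state (numeric probe)."""
    rng = np.random.default_rng(seed)
    depends = np.zeros(model.K, bool)
    for _ in range(n_probe):
        x = rng.uniform(0.5, 1.5, model.K)
        G0, h0 = model.gmat(x), model.hvec(x)
        for k in hidden_idx:
            xp = x.copy()
            xp[k] *= 1.37 + rng.uniform(0, 1)
            depends |= np.any(model.gmat(xp) != G0, axis=1) | (model.hvec(xp) != h0)
    return depends


def default_initial_guess(
    model: LinearODEModel,
    smoothing: CellSmoothing,
    measurement: MeasurementModel,
    fallback: float = 1.0,
) -> np.ndarray:
    """Initial beta from ODE rows that involve observed states only.

    Rows whose design entries and offset depend solely on observed states
    form a self-contained least-squares problem; parameters appearing in
    those rows are estimated by OLS, the rest default to ``fallback`` (one in
    model units).  Fully observed systems reduce to the plain OLS estimate.
    """
    obs_idx = measurement.observed_indices
    hidden_idx = np.setdiff1d(np.arange(model.K), obs_idx)
    usable = ~_row_depends_on_hidden(model, hidden_idx)
    usable[hidden_idx] = False  # the response xdot_k needs state k smoothed
    beta0 = np.full(model.P, float(fallback))
    if not usable.any():
        return beta0
    obs_pos = {k: r for r, k in enumerate(obs_idx)}
    T = smoothing.xhat.shape[0]
    rows_G, rows_d = [], []
    for j in range(T):
        x = np.zeros(model.K)
        x[obs_idx] = smoothing.xhat[j]
        G = model.gmat(x)
        h = model.hvec(x)
        for k in np.nonzero(usable)[0]:
            rows_G.append(G[k])
            rows_d.append(smoothing.xdot_hat[j, obs_pos[k]] - h[k])
    Gu = np.array(rows_G)
    du = np.array(rows_d)
    est_cols = np.nonzero(np.abs(Gu).sum(axis=0) > 0)[0]
    if est_cols.size:
        sol, *_ = np.linalg.lstsq(Gu[:, est_cols], du, rcond=None)
        beta0[est_cols] = sol
    return beta0


def integrate_hidden(
    model: LinearODEModel,
    beta: np.ndarray,
    tgrid: np.ndarray,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> HiddenStateEstimate:
    """Integrate the system together with its forward sensitivities.

    The augmented system solves ``xdot = f(x; beta)`` and ``Sdot = J(x) S +
    g(x)`` with ``S(0) = 0`` (initial conditions are known, hence
    beta-independent).  Gradients are the rhs along the solution.
    """
    beta = np.asarray(beta, float)
    tgrid = np.asarray(tgrid, float)
    K, P = model.K, model.P

    def aug_rhs(t, z):
        x = z[:K]
        S = z[K:].reshape(K, P)
        J = model.jacobian_x(x, beta)
        dz = np.empty_like(z)
        dz[:K] = model.rhs(x, beta)
        dz[K:] = (J @ S + model.gmat(x)).ravel()
        return dz

    def aug_jac(t, z):
        # Block Jacobian ignoring the (Hessian-driven) dSdot/dx coupling:
        # inexact Newton matrices only slow the implicit solver, never bias
        # the solution, and this cuts the rhs evaluations several-fold.
        J = model.jacobian_x(z[:K], beta)
        Jb = np.zeros((K * (P + 1), K * (P + 1)))
        Jb[:K, :K] = J
        for p in range(P):
            idx = K + np.arange(K) * P + p
            Jb[np.ix_(idx, idx)] = J
        return Jb

    z0 = np.concatenate([model.x0, np.zeros(K * P)])
    # implicit BDF with the block Jacobian pays off only for larger augmented
    # systems; small ones are cheaper under LSODA's adaptive switching
    use_bdf = model.jac_x is not None and K * (P + 1) >= 30
    with np.errstate(over="raise", invalid="raise"):
        try:
            sol = solve_ivp(
                aug_rhs,
                (tgrid[0], tgrid[-1]),
                z0,
                t_eval=tgrid,
                method="BDF" if use_bdf else "LSODA",
                jac=aug_jac if use_bdf else None,
                rtol=rtol,
                atol=atol,
            )
        except FloatingPointError as e:
            raise IntegrationError(f"sensitivity integration overflowed: {e}", beta=beta)
    if not sol.success or sol.y.shape[1] != len(tgrid):
        raise IntegrationError(
            f"sensitivity integration failed: {sol.message}", beta=beta
        )
    x = sol.y[:K].T
    S = sol.y[K:].T.reshape(len(tgrid), K, P)
    xdot = np.array([model.rhs(x[j], beta) for j in range(len(tgrid))])
    return HiddenStateEstimate(x=x, xdot=xdot, S=S, beta=beta)


def propagate_hidden_uncertainty(
    est: HiddenStateEstimate, C: np.ndarray, hidden_idx: np.ndarray
) -> np.ndarray:
    """Per-time-point covariance of the hidden-state values induced by C.

    First-order delta method through the ODE solution: ``Cov x_hid(t_j) =
    S_hid(t_j) C S_hid(t_j)'``.  Returns a (T, K_hid, K_hid) array.
    """
    S_hid = est.S[:, hidden_idx, :]
    return np.einsum("jkp,pq,jlq->jkl", S_hid, np.asarray(C, float), S_hid)


def _mixed_states(smoothing: CellSmoothing, est: HiddenStateEstimate, obs_idx):
    xmix = est.x.copy()
    xmix[:, obs_idx] = smoothing.xhat
    return xmix


def _observed_row_system(
    model: LinearODEModel,
    smoothing: CellSmoothing,
    est: HiddenStateEstimate,
    beta: np.ndarray,
    obs_idx: np.ndarray,
    hidden_idx: np.ndarray,
):
    """Sensitivity-corrected design, response, and smoothing propagation maps.

    For observed state k the regression row reads ``xdot_hat_k - h_k(x~) +
    (J_k,hid S_hid) beta = (g_k(x~) + J_k,hid S_hid) beta'`` where x~ mixes
    smoothed observed states with integrated hidden ones.  Also returns, per
    observed state, the first-order map from its spline-coefficient errors to
    the row residuals (gradient term minus Jacobian-coupled value terms).
    """
    T = est.x.shape[0]
    Kobs = len(obs_idx)
    fits = smoothing.fits
    xmix = _mixed_states(smoothing, est, obs_idx)
    G = np.empty((T * Kobs, model.P))
    d = np.empty(T * Kobs)
    A_c = [np.zeros((T * Kobs, f.basis.n_basis)) for f in fits]
    for j in range(T):
        Gj = model.gmat(xmix[j])
        hj = model.hvec(xmix[j])
        Jj = model.jacobian_x(xmix[j], beta)
        corr = (
            Jj[:, hidden_idx] @ est.S[j][hidden_idx]
            if hidden_idx.size
            else np.zeros((model.K, model.P))
        )
        for r, k in enumerate(obs_idx):
            row = j * Kobs + r
            G[row] = Gj[k] + corr[k]
            d[row] = smoothing.xdot_hat[j, r] - hj[k] + corr[k] @ beta
            A_c[r][row] += fits[r].basis.Bdot[j]
            for r2, l in enumerate(obs_idx):
                A_c[r2][row] -= Jj[k, l] * fits[r2].basis.B[j]
    return G, d, A_c, xmix


def _smoothing_covariance(A_c, fits, ridge_scale=_RIDGE_SCALE):
    n = A_c[0].shape[0]
    V = np.zeros((n, n))
    for M, f in zip(A_c, fits):
        V += M @ f.coef_cov @ M.T
    V[np.diag_indices(n)] += ridge_scale * max(np.trace(V) / n, 1e-300)
    return 0.5 * (V + V.T)


def partial_residual_covariance(
    model: LinearODEModel,
    smoothing: CellSmoothing,
    est: HiddenStateEstimate,
    beta: np.ndarray,
    C: np.ndarray | None,
    measurement: MeasurementModel,
    ridge_scale: float = _RIDGE_SCALE,
) -> np.ndarray:
    """Residual covariance over the full (T K) grid, hidden rows included.

    Observed-state spline-coefficient errors propagate exactly as in the
    fully observed case; hidden-state values carry the parameter uncertainty
    ``C`` through the sensitivities (values move by ``S_hid dbeta``, hidden
    gradients by ``(g_hid + J_hid S) dbeta``).  Used for reporting and for
    Monte-Carlo validation of the uncertainty model.
    """
    obs_idx = measurement.observed_indices
    hidden_idx = np.setdiff1d(np.arange(model.K), obs_idx)
    K, P = model.K, model.P
    T = est.x.shape[0]
    n = T * K
    fits = smoothing.fits
    nb = [f.basis.n_basis for f in fits]
    offs = np.concatenate([[0], np.cumsum(nb)])
    A_c = np.zeros((n, offs[-1]))
    A_b = np.zeros((n, P))
    obs_pos = {k: r for r, k in enumerate(obs_idx)}
    xmix = _mixed_states(smoothing, est, obs_idx)
    for j in range(T):
        J = model.jacobian_x(xmix[j], beta)
        G = model.gmat(xmix[j])
        Sj = est.S[j]
        for k in range(K):
            row = j * K + k
            if k in obs_pos:
                r = obs_pos[k]
                A_c[row, offs[r] : offs[r + 1]] += fits[r].basis.Bdot[j]
            else:
                A_b[row] += G[k] + J[k] @ Sj
            for l in range(K):
                if l in obs_pos:
                    r = obs_pos[l]
                    A_c[row, offs[r] : offs[r + 1]] -= J[k, l] * fits[r].basis.B[j]
                else:
                    A_b[row] -= J[k, l] * Sj[l]
    V = np.zeros((n, n))
    for r, f in enumerate(fits):
        Mk = A_c[:, offs[r] : offs[r + 1]]
        V += Mk @ f.coef_cov @ Mk.T
    if C is not None:
        V += A_b @ np.asarray(C, float) @ A_b.T
    V[np.diag_indices(n)] += ridge_scale * max(np.trace(V) / n, 1e-300)
    return 0.5 * (V + V.T)


def _clamp_step(beta_old: np.ndarray, beta_new: np.ndarray, factor: float) -> np.ndarray:
    """Limit the per-component relative change to guard early wild steps."""
    lo = np.minimum(beta_old / factor, beta_old * factor)
    hi = np.maximum(beta_old / factor, beta_old * factor)
    pad = 0.1 * np.abs(beta_old) + 0.01 * np.mean(np.abs(beta_old)) + 1e-12
    return np.clip(beta_new, lo - pad, hi + pad)


def stage1_partial(
    model: LinearODEModel,
    smoothing: CellSmoothing,
    measurement: MeasurementModel,
    tgrid: np.ndarray,
    beta0: np.ndarray | None = None,
    tol: float = 1e-2,
    max_iter: int = 10,
    rtol: float = 1e-6,
    step_clamp: float = 3.0,
    cell_id: str | None = None,
) -> IndividualEstimate:
    """Fixed-point iteration for one partially observed cell.

    Each round integrates the system and its sensitivities at the current
    beta (one augmented integration), assembles the sensitivity-corrected
    gradient-matching problem on the observed rows, and re-solves it under
    inverse-variance weights from the smoothing-propagated residual
    covariance.  Stops when the relative beta change falls below ``tol`` or
    after ``max_iter`` rounds; non-convergence is flagged, never raised.
    If no states are hidden the problem degenerates to full-information
    FGLS and is delegated to it.
    """
    obs_idx = measurement.observed_indices
    hidden_idx = np.setdiff1d(np.arange(model.K), obs_idx)
    if hidden_idx.size == 0:
        # fully observed: the scheme degenerates to plain FGLS
        from .gls import fgls_fit

        fits = [smoothing.fits[r] for r in np.argsort(obs_idx)]
        return fgls_fit(model, fits, cell_id=cell_id)
    if beta0 is None:
        beta0 = default_initial_guess(model, smoothing, measurement)
    beta = np.asarray(beta0, float)

    n_int = 0
    converged = False
    history = [beta.copy()]
    G = d = A_c = None
    W = None
    it = 0
    for it in range(1, max_iter + 1):
        est = None
        for attempt in range(4):  # back off towards the last iterate on blow-up
            try:
                est = integrate_hidden(model, beta, tgrid, rtol=rtol)
                n_int += 1
                break
            except IntegrationError:
                if len(history) < 2 or attempt == 3:
                    raise
                beta = 0.5 * (beta + history[-2])
        G, d, A_c, _ = _observed_row_system(
            model, smoothing, est, beta, obs_idx, hidden_idx
        )
        Vsm = _smoothing_covariance(A_c, smoothing.fits)
        W = 1.0 / np.diag(Vsm)
        sys = GLSSystem(Gmat=G, dvec=d, V=np.diag(1.0 / W))
        try:
            step = gls_solve(sys)
        except np.linalg.LinAlgError:
            # transiently collinear design far from the fixed point: take the
            # minimal-norm weighted solution; the step clamp bounds it
            sw = np.sqrt(W)
            step, *_ = np.linalg.lstsq(G * sw[:, None], d * sw, rcond=1e-10)
        beta_new = _clamp_step(beta, step, step_clamp)
        history.append(beta_new.copy())
        delta = np.linalg.norm(beta_new - beta) / max(np.linalg.norm(beta), 1e-300)
        beta = beta_new
        if delta < tol or hidden_idx.size == 0:
            converged = True
            break
    Vsm = _smoothing_covariance(A_c, smoothing.fits)
    C = sandwich_covariance(G, W, Vsm)
    return IndividualEstimate(
        beta_hat=beta,
        C=C,
        n_iter=it,
        converged=converged,
        history=history,
        cell_id=cell_id,
        n_integrations=n_int,
    )
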