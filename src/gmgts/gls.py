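"""Stage I gradient matching with full state information.

With the right-hand side linear in the parameters, equating smoothed
gradients to the model rates yields the linear regression problem

    xdot_hat(t_j) - h(xhat(t_j)) = g(xhat(t_j)) beta + residual,

stacked over time points.  The residual covariance is unknown (it depends on
the smoothing uncertainty of both sides, hence on beta through the state
Jacobian), so the fit alternates generalized least squares with a first-order
delta-method update of that covariance — a feasible GLS scheme.  The
parameter covariance at convergence is ``(G' V^-1 G)^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .models import LinearODEModel
from .smoothing import SplineFit

__all__ = [
    "GLSSystem",
    "IndividualEstimate",
    "assemble_system",
    "gls_solve",
    "residual_covariance",
    "fgls_fit",
]

_RIDGE_SCALE = 1e-8


@dataclass
class GLSSystem:
    """The stacked linear regression problem of one cell.

    Rows are ordered time-major: row ``j*K + k`` is state ``k`` at time
    ``t_j``.  ``V`` is the current residual covariance.
    """

    Gmat: np.ndarray
    dvec: np.ndarray
    V: np.ndarray


@dataclass
class IndividualEstimate:
    """Cell-specific parameter estimate with covariance and diagnostics."""

    beta_hat: np.ndarray
    C: np.ndarray
    n_iter: int = 0
    converged: bool = True
    history: list = field(default_factory=list)
    cell_id: str | None = None
    n_integrations: int = 0

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "beta_hat": self.beta_hat.tolist(),
            "C": self.C.tolist(),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "n_integrations": int(self.n_integrations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IndividualEstimate":
        return cls(
            beta_hat=np.asarray(d["beta_hat"], float),
            C=np.asarray(d["C"], float),
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", True),
            cell_id=d.get("cell_id"),
            n_integrations=d.get("n_integrations", 0),
        )


def _stack_design(model: LinearODEModel, xhat: np.ndarray, xdot_hat: np.ndarray):
    T = xhat.shape[0]
    G = np.empty((T * model.K, model.P))
    d = np.empty(T * model.K)
    for j in range(T):
        G[j * model.K : (j + 1) * model.K] = model.gmat(xhat[j])
        d[j * model.K : (j + 1) * model.K] = xdot_hat[j] - model.hvec(xhat[j])
    return G, d


def assemble_system(model: LinearODEModel, fits: list[SplineFit]) -> GLSSystem:
    """Assemble the regression problem from per-state spline fits.

    Requires a fit for every state (full observation).  The residual
    covariance is initialized to the identity, so the first GLS solve is
    ordinary least squares.
    """
    if len(fits) != model.K:
        raise ValueError(
            f"need one spline fit per state: got {len(fits)}, expected {model.K}"
        )
    xhat = np.column_stack([f.fitted for f in fits])
    xdot_hat = np.column_stack([f.fitted_deriv for f in fits])
    G, d = _stack_design(model, xhat, xdot_hat)
    return GLSSystem(Gmat=G, dvec=d, V=np.eye(len(d)))


def gls_solve(sys: GLSSystem) -> np.ndarray:
    """Generalized least-squares solution ``(G'V^-1 G)^-1 G'V^-1 d``.

    ``V`` is handled through a Cholesky factorization (whitening); the full
    TK x TK inverse is never formed explicitly.
    """
    G, d, V = sys.Gmat, sys.dvec, sys.V
    cf = cho_factor(V, lower=True)
    Gw = cho_solve(cf, G)
    A = G.T @ Gw
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        corr = np.corrcoef(G.T) if G.shape[1] > 1 else np.ones((1, 1))
        np.fill_diagonal(corr, 0.0)
        worst = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (cond={cond:.2e}); "
            f"columns {worst[0]} and {worst[1]} are nearly collinear"
        )
    return np.linalg.solve(A, G.T @ cho_solve(cf, d))


def _coef_cov_blocks(fits: list[SplineFit]) -> list[np.ndarray]:
    return [f.coef_cov for f in fits]


def propagation_matrix(
    model: LinearODEModel,
    fits: list[SplineFit],
    beta: np.ndarray,
    xhat: np.ndarray | None = None,
) -> np.ndarray:
    """First-order map from spline-coefficient errors to regression residuals.

    A coefficient perturbation ``dc_k`` moves state k by ``B dc_k`` and its
    gradient by ``Bdot dc_k``; through the state Jacobian ``J = df/dx`` this
    perturbs the residual row (j, k) by ``Bdot[j] dc_k - sum_l J_kl B[j] dc_l``.
    Returns the (T K) x (K n_basis) matrix of that linear map (coefficient
    blocks ordered by state).
    """
    K = model.K
    T = fits[0].fitted.shape[0]
    if xhat is None:
        xhat = np.column_stack([f.fitted for f in fits])
    nb = [f.basis.n_basis for f in fits]
    offs = np.concatenate([[0], np.cumsum(nb)])
    M = np.zeros((T * K, offs[-1]))
    for j in range(T):
        J = model.jacobian_x(xhat[j], beta)
        for k in range(K):
            row = j * K + k
            M[row, offs[k] : offs[k + 1]] = fits[k].basis.Bdot[j]
            for l in range(K):
                M[row, offs[l] : offs[l + 1]] -= J[k, l] * fits[l].basis.B[j]
    return M


def residual_covariance(
    model: LinearODEModel,
    fits: list[SplineFit],
    beta: np.ndarray,
    ridge_scale: float = _RIDGE_SCALE,
) -> np.ndarray:
    """Delta-method approximation of the residual covariance Var(Delta).

    ``V = M Sigma_c M' + ridge I`` where ``Sigma_c`` is the block-diagonal
    spline-coefficient covariance (states are independently measured) and
    ``M`` the propagation matrix at the current beta.  The small ridge keeps
    V positive definite when the smoother covariance is near-singular.
    """
    M = propagation_matrix(model, fits, np.asarray(beta, float))
    blocks = _coef_cov_blocks(fits)
    nb = [b.shape[0] for b in blocks]
    offs = np.concatenate([[0], np.cumsum(nb)])
    V = np.zeros((M.shape[0], M.shape[0]))
    for k, blk in enumerate(blocks):
        Mk = M[:, offs[k] : offs[k + 1]]
        V += Mk @ blk @ Mk.T
    n = V.shape[0]
    ridge = ridge_scale * max(np.trace(V) / n, 1e-300)
    V[np.diag_indices(n)] += ridge
    return 0.5 * (V + V.T)


def sandwich_covariance(G: np.ndarray, W: np.ndarray, Vfull: np.ndarray) -> np.ndarray:
    """Covariance of a weighted LS estimate under residual covariance Vfull.

    With weights ``W`` (a vector, the inverse working variances),
    ``Cov(beta) = A^-1 G'W Vfull W G A^-1`` where ``A = G'WG``.  When
    ``W = Vfull^-1`` this collapses to ``(G' Vfull^-1 G)^-1``.
    """
    GW = G * W[:, None]
    A = GW.T @ G
    Ainv = np.linalg.inv(A)
    C = Ainv @ (GW.T @ Vfull @ GW) @ Ainv
    return 0.5 * (C + C.T)


def fgls_fit(
    model: LinearODEModel,
    fits: list[SplineFit],
    tol: float = 1e-3,
    max_iter: int = 20,
    cell_id: str | None = None,
) -> IndividualEstimate:
    """Feasible GLS for one fully observed cell.

    Alternates the GLS solve with the residual-covariance update until the
    relative l2 change of beta drops below ``tol``.  The first iterate (V=I)
    is the ordinary least-squares solution.  The working weights are the
    inverse *diagonal* of the delta-method residual covariance: its
    off-diagonal structure is low-rank (T points share n_basis spline
    coefficients per state) and omits spline bias, so inverting it in full
    lets GLS chase near-null directions and destabilizes the iteration.  The
    parameter covariance is the sandwich estimate under the full V, which
    retains the residual correlations.
    """
    sys = assemble_system(model, fits)
    beta = gls_solve(sys)
    history = [beta.copy()]
    converged = False
    it = 1
    Vfull = residual_covariance(model, fits, beta)
    for it in range(2, max_iter + 1):
        sys.V = np.diag(np.diag(Vfull))
        beta_new = gls_solve(sys)
        history.append(beta_new.copy())
        delta = np.linalg.norm(beta_new - beta) / max(np.linalg.norm(beta), 1e-300)
        beta = beta_new
        if delta < tol:
            converged = True
            break
        Vfull = residual_covariance(model, fits, beta)
    C = sandwich_covariance(sys.Gmat, 1.0 / np.diag(Vfull), Vfull)
    return IndividualEstimate(
        beta_hat=beta,
        C=C,
        n_iter=it,
        converged=converged,
        history=history,
        cell_id=cell_id,
    )
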