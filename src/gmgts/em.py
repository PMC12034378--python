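"""Stage II: population-parameter estimation by Expectation-Maximization.

The measurement model for stage II treats each cell's stage-I estimate as a
noisy observation of its true parameter vector:

    beta_hat_i | beta_i ~ N(beta_i, C_i),      beta_i ~ N(b, D).

EM deconvolves the estimation noise C_i from the observed spread of the
beta_hat_i, avoiding the inflated covariance of the naive sample statistics.
A log-normal population is handled by a delta-method transform of the
individual estimates to log scale followed by the same EM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .gls import IndividualEstimate

__all__ = ["PopulationEstimate", "em_fit", "marginal_loglik", "lognormal_fit"]


@dataclass
class PopulationEstimate:
    """Estimated population distribution with EM diagnostics."""

    family: str
    b_hat: np.ndarray
    D_hat: np.ndarray
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True

    @property
    def P(self) -> int:
        return self.b_hat.shape[0]

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "b_hat": self.b_hat.tolist(),
            "D_hat": self.D_hat.tolist(),
            "loglik_trace": [float(v) for v in self.loglik_trace],
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationEstimate":
        return cls(
            family=d["family"],
            b_hat=np.asarray(d["b_hat"], float),
            D_hat=np.asarray(d["D_hat"], float),
            loglik_trace=list(d.get("loglik_trace", [])),
            n_iter=d.get("n_iter", 0),
            converged=d.get("converged", True),
        )


def _check_psd(estimates: list[IndividualEstimate]) -> None:
    for e in estimates:
        w = np.linalg.eigvalsh(0.5 * (e.C + e.C.T))
        if w.min() < -1e-8 * max(1.0, abs(w).max()):
            raise ValueError(
                f"individual covariance of cell {e.cell_id!r} is not PSD "
                f"(min eigenvalue {w.min():.3e})"
            )


def _floor_psd(D: np.ndarray, rel_floor: float = 1e-10) -> np.ndarray:
    D = 0.5 * (D + D.T)
    w, U = np.linalg.eigh(D)
    floor = rel_floor * max(np.trace(D), 0.0) / D.shape[0]
    w = np.maximum(w, floor)
    return (U * w) @ U.T


def marginal_loglik(
    estimates: list[IndividualEstimate], b: np.ndarray, D: np.ndarray
) -> float:
    """Marginal log-likelihood sum_i log N(beta_hat_i; b, D + C_i)."""
    b = np.asarray(b, float)
    D = np.asarray(D, float)
    P = len(b)
    total = 0.0
    for e in estimates:
        S = D + e.C
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"D + C is singular for cell {e.cell_id!r}"
            )
        r = e.beta_hat - b
        total += -0.5 * (P * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(S, r))
    return float(total)


def em_fit(
    estimates: list[IndividualEstimate],
    tol: float = 1e-6,
    max_iter: int = 1000,
    family: str = "normal",
) -> PopulationEstimate:
    """EM for (b, D) given individual estimates and their covariances.

    E-step: posterior mean ``mu_i = b + D (D + C_i)^-1 (beta_hat_i - b)`` and
    covariance ``Sigma_i = D - D (D + C_i)^-1 D`` for each cell's true
    parameters.  M-step: ``b = mean(mu_i)``, ``D = mean(Sigma_i +
    (mu_i - b)(mu_i - b)')``.  Initialized at the median and the naive sample
    covariance; iterates until the relative change of (b, D) drops below
    ``tol``.  With all ``C_i = 0`` the first M-step already returns the naive
    sample statistics.
    """
    if len(estimates) < 2:
        raise ValueError("EM needs at least two cells")
    _check_psd(estimates)
    bhats = np.array([e.beta_hat for e in estimates])
    N, P = bhats.shape
    b = np.median(bhats, axis=0)
    centered = bhats - bhats.mean(axis=0)
    D = _floor_psd(centered.T @ centered / N)

    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mus = np.empty_like(bhats)
        Sigmas = np.zeros((N, P, P))
        for i, e in enumerate(estimates):
            S = D + e.C
            gain = np.linalg.solve(S.T, D.T).T  # D (D + C_i)^-1
            mus[i] = b + gain @ (bhats[i] - b)
            Sigmas[i] = D - gain @ D
        b_new = mus.mean(axis=0)
        dev = mus - b_new
        D_new = _floor_psd(Sigmas.mean(axis=0) + dev.T @ dev / N)
        trace.append(marginal_loglik(estimates, b_new, D_new))
        num = np.linalg.norm(b_new - b) + np.linalg.norm(D_new - D)
        den = max(np.linalg.norm(b) + np.linalg.norm(D), 1e-300)
        b, D = b_new, D_new
        if num / den < tol:
            converged = True
            break
    return PopulationEstimate(
        family=family,
        b_hat=b,
        D_hat=D,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
    )


def lognormal_fit(
    estimates: list[IndividualEstimate],
    tol: float = 1e-6,
    max_iter: int = 1000,
    clip: float = 1e-12,
) -> PopulationEstimate:
    """Approximate EM for a log-normal population.

    Individual estimates are transformed to log scale with the delta method
    (``m_i = log beta_hat_i``, ``C_i^log = diag(1/beta_hat_i) C_i
    diag(1/beta_hat_i)``), then the normal-family EM runs on the transformed
    estimates.  The returned (b, D) are the log-mean and log-covariance.
    Components at or below ``clip`` (after clipping negative stage-I values)
    are rejected.
    """
    bad = [
        e.cell_id
        for e in estimates
        if np.any(np.asarray(e.beta_hat) <= clip)
    ]
    if bad:
        raise ValueError(
            f"nonpositive parameter estimates for cells {bad}; a log-normal "
            "population requires positive stage-I estimates"
        )
    log_est = []
    for e in estimates:
        scale = np.diag(1.0 / e.beta_hat)
        log_est.append(
            IndividualEstimate(
                beta_hat=np.log(e.beta_hat),
                C=scale @ e.C @ scale,
                n_iter=e.n_iter,
                converged=e.converged,
                cell_id=e.cell_id,
            )
        )
    out = em_fit(log_est, tol=tol, max_iter=max_iter, family="lognormal")
    return out
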