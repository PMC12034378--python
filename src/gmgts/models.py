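"""Core model types for mixed-effects ODE systems.

An individual cell follows a deterministic ODE ``xdot = f(x; beta)`` with a
known initial condition; the cell-specific kinetic parameter vector ``beta``
is drawn from a population distribution (normal or log-normal).  Gradient
matching requires the right-hand side to be *linear in the parameters*,
``f(x; beta) = g(x) beta + h(x)``, which holds automatically for mass-action
kinetics.  Measurements select a subset of states and carry additive plus
multiplicative Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ODEModel",
    "LinearODEModel",
    "MeasurementModel",
    "PopulationDistribution",
    "CellMeasurements",
    "PopulationDataset",
    "IntegrationError",
    "rhs",
    "sample_parameters",
    "simulate_individual",
    "observe",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the offending beta."""

    def __init__(self, message: str, beta: np.ndarray | None = None):
        super().__init__(message)
        self.beta = None if beta is None else np.asarray(beta, float)


@dataclass
class ODEModel:
    """A parameterized ODE system ``xdot = f(x; beta)`` with known x(0).

    This base form makes no structural assumption about how ``beta`` enters
    the right-hand side; it is sufficient for simulation and for
    trajectory-matching fits.
    """

    K: int
    P: int
    state_names: Sequence[str]
    param_names: Sequence[str]
    x0: np.ndarray
    f: Callable[[np.ndarray, np.ndarray], np.ndarray]
    fixed_params: dict = field(default_factory=dict)
    jac_x: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    name: str = "ode_model"

    def __post_init__(self):
        self.x0 = np.asarray(self.x0, float)
        if self.x0.shape != (self.K,):
            raise ValueError(
                f"x0 has shape {self.x0.shape}, expected ({self.K},)"
            )
        if len(self.state_names) != self.K or len(self.param_names) != self.P:
            raise ValueError("state_names/param_names length mismatch with K/P")

    def rhs(self, x: np.ndarray, beta: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        beta = np.asarray(beta, float)
        if x.shape[-1] != self.K:
            raise ValueError(f"state x has length {x.shape[-1]}, expected K={self.K}")
        if beta.shape != (self.P,):
            raise ValueError(f"beta has shape {beta.shape}, expected ({self.P},)")
        return self.f(x, beta)

    def jacobian_x(self, x: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """State Jacobian df/dx; analytic if provided, else central differences."""
        if self.jac_x is not None:
            return np.asarray(self.jac_x(np.asarray(x, float), np.asarray(beta, float)))
        x = np.asarray(x, float)
        J = np.empty((self.K, self.K))
        h = 1e-6 * np.maximum(np.abs(x), 1.0)
        for k in range(self.K):
            xp, xm = x.copy(), x.copy()
            xp[k] += h[k]
            xm[k] -= h[k]
            J[:, k] = (self.rhs(xp, beta) - self.rhs(xm, beta)) / (2 * h[k])
        return J


@dataclass
class LinearODEModel(ODEModel):
    """ODE system with right-hand side linear in the parameters.

    ``rhs(x, beta) = g(x) @ beta + h(x)`` where ``g`` maps a state vector to
    a (K, P) matrix and ``h`` to a (K,) vector; neither depends on beta.
    """

    g: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]
    h: Callable[[np.ndarray], np.ndarray] = None  # type: ignore[assignment]

    def __init__(
        self,
        K: int,
        P: int,
        state_names: Sequence[str],
        param_names: Sequence[str],
        x0: np.ndarray,
        g: Callable[[np.ndarray], np.ndarray],
        h: Callable[[np.ndarray], np.ndarray],
        fixed_params: dict | None = None,
        jac_x: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
        name: str = "linear_ode_model",
    ):
        self.g = g
        self.h = h
        super().__init__(
            K=K,
            P=P,
            state_names=state_names,
            param_names=param_names,
            x0=np.asarray(x0, float),
            f=lambda x, beta: np.asarray(g(x)) @ beta + np.asarray(h(x)),
            fixed_params=fixed_params or {},
            jac_x=jac_x,
            name=name,
        )

    def gmat(self, x: np.ndarray) -> np.ndarray:
        G = np.asarray(self.g(np.asarray(x, float)), float)
        if G.shape != (self.K, self.P):
            raise ValueError(f"g(x) has shape {G.shape}, expected ({self.K}, {self.P})")
        return G

    def hvec(self, x: np.ndarray) -> np.ndarray:
        h = np.asarray(self.h(np.asarray(x, float)), float)
        if h.shape != (self.K,):
            raise ValueError(f"h(x) has shape {h.shape}, expected ({self.K},)")
        return h


def rhs(model: ODEModel, x: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Evaluate the model right-hand side at state ``x`` and parameters ``beta``."""
    return model.rhs(x, beta)


@dataclass
class MeasurementModel:
    """Selection of observed states plus the noise model.

    ``y(t_j) = Q x(t_j) + eps`` with ``Var eps_k = sigma_k^2 + tau_k^2 x_k^2``
    independently across states and time points.  ``Q`` is a binary selection
    matrix: each row picks one distinct state.
    """

    Q: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray

    def __post_init__(self):
        self.Q = np.asarray(self.Q, float)
        self.sigma = np.atleast_1d(np.asarray(self.sigma, float))
        self.tau = np.atleast_1d(np.asarray(self.tau, float))
        K_obs = self.Q.shape[0]
        if not np.all(np.isin(self.Q, [0.0, 1.0])):
            raise ValueError("Q must be binary")
        if not np.all(self.Q.sum(axis=1) == 1):
            raise ValueError("every row of Q must contain exactly one 1")
        idx = self.observed_indices
        if len(set(idx)) != K_obs:
            raise ValueError("rows of Q must select distinct states")
        if self.sigma.shape != (K_obs,) or self.tau.shape != (K_obs,):
            raise ValueError("sigma/tau must have one entry per observed state")
        if np.any(self.sigma < 0) or np.any(self.tau < 0):
            raise ValueError("sigma and tau must be nonnegative")

    @property
    def K_obs(self) -> int:
        return self.Q.shape[0]

    @property
    def observed_indices(self) -> np.ndarray:
        return np.argmax(self.Q, axis=1)

    @classmethod
    def identity(cls, K: int, sigma=0.0, tau=0.05) -> "MeasurementModel":
        return cls(np.eye(K), np.full(K, float(sigma)), np.full(K, float(tau)))

    @classmethod
    def select(cls, K: int, observed: Sequence[int], sigma=0.0, tau=0.05) -> "MeasurementModel":
        Q = np.zeros((len(observed), K))
        for r, k in enumerate(observed):
            Q[r, k] = 1.0
        n = len(observed)
        return cls(Q, np.full(n, float(sigma)), np.full(n, float(tau)))


@dataclass
class PopulationDistribution:
    """Population law of the cell-specific parameters.

    For the normal family, ``beta_i ~ N(b, D)``.  For the log-normal family,
    ``log beta_i ~ N(b, D)`` — i.e. ``b`` and ``D`` are the log-mean and
    log-covariance.
    """

    family: str
    b: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        self.b = np.asarray(self.b, float)
        self.D = np.asarray(self.D, float)
        P = self.b.shape[0]
        if self.D.shape != (P, P):
            raise ValueError("D must be P x P")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("D must be symmetric")
        if np.min(np.linalg.eigvalsh(self.D)) < -1e-10 * max(1.0, np.trace(self.D)):
            raise ValueError("D must be positive semi-definite")

    @property
    def P(self) -> int:
        return self.b.shape[0]


@dataclass
class CellMeasurements:
    """Noisy observations of one cell on a shared time grid."""

    cell_id: str
    t: np.ndarray
    y: np.ndarray
    true_beta: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.y = np.atleast_2d(np.asarray(self.y, float))
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.y.shape[0] != self.t.shape[0]:
            raise ValueError("y must have one row per time point")
        if self.true_beta is not None:
            self.true_beta = np.asarray(self.true_beta, float)

    @property
    def T(self) -> int:
        return self.t.shape[0]

    @property
    def K_obs(self) -> int:
        return self.y.shape[1]


@dataclass
class PopulationDataset:
    """A population of cells measured under a common design."""

    cells: list[CellMeasurements]
    model: ODEModel
    measurement: MeasurementModel
    generating_distribution: PopulationDistribution | None = None
    seed: int | None = None
    scenario: str | None = None

    def __post_init__(self):
        if len(self.cells) < 1:
            raise ValueError("dataset must contain at least one cell")
        kobs = {c.K_obs for c in self.cells}
        if len(kobs) != 1:
            raise ValueError("all cells must share the number of observed states")

    @property
    def N(self) -> int:
        return len(self.cells)

    @property
    def true_betas(self) -> np.ndarray | None:
        if any(c.true_beta is None for c in self.cells):
            return None
        return np.array([c.true_beta for c in self.cells])


def sample_parameters(
    dist: PopulationDistribution, N: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw N i.i.d. parameter vectors from the population distribution.

    Returns an (N, P) matrix.  For the log-normal family the draws are
    exponentiated normal variates.  Uses an eigendecomposition square root so
    that singular (degenerate) covariances are handled exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, U = np.linalg.eigh(dist.D)
    if np.min(w) < -1e-10 * max(1.0, np.trace(dist.D)):
        raise ValueError("D must be positive semi-definite")
    L = U * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((N, dist.P))
    draws = dist.b + z @ L.T
    if dist.family == "lognormal":
        draws = np.exp(draws)
    return draws


def simulate_individual(
    model: ODEModel,
    beta: np.ndarray,
    tgrid: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> np.ndarray:
    """Integrate one cell's ODE on ``tgrid`` from the model's initial condition.

    Returns the (T, K) solution matrix.  The default tolerances are tight for
    data generation; inference loops pass looser ones.
    """
    beta = np.asarray(beta, float)
    tgrid = np.asarray(tgrid, float)
    if np.any(np.diff(tgrid) <= 0):
        raise ValueError("tgrid must be strictly increasing")
    with np.errstate(over="raise", invalid="raise"):
        try:
            sol = solve_ivp(
                lambda t, x: model.rhs(x, beta),
                (tgrid[0], tgrid[-1]),
                model.x0,
                t_eval=tgrid,
                method=method,
                rtol=rtol,
                atol=atol,
            )
        except FloatingPointError as e:
            raise IntegrationError(f"ODE solution overflowed: {e}", beta=beta)
    if not sol.success or sol.y.shape[1] != len(tgrid):
        raise IntegrationError(f"ODE integration failed: {sol.message}", beta=beta)
    return sol.y.T


def observe(
    traj: np.ndarray, meas: MeasurementModel, seed: int | np.random.Generator
) -> np.ndarray:
    """Apply the selection matrix and add heteroscedastic Gaussian noise.

    Noise variance at each point is ``sigma_k^2 + tau_k^2 x_k^2`` with the
    true (selected) state value x_k, independent across states and times.
    """
    traj = np.asarray(traj, float)
    if not np.all(np.isfinite(traj)):
        raise ValueError("trajectory contains non-finite values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x_obs = traj @ meas.Q.T
    sd = np.sqrt(meas.sigma**2 + meas.tau**2 * x_obs**2)
    return x_obs + rng.standard_normal(x_obs.shape) * sd
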