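"""Trajectory-matching stage I (the classical GTS baseline).

Each cell's parameters are estimated by weighted nonlinear least squares
against the integrated ODE solution, with multistart initialization to
escape local optima.  This is the expensive route that gradient matching
replaces; it shares stage II (EM) with the gradient-matching pipeline and is
kept for accuracy and cost comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .models import CellMeasurements, IntegrationError, MeasurementModel, ODEModel, simulate_individual
from .smoothing import CellSmoothing, NoiseEstimate, _weight_floor

__all__ = ["TrajectoryFitResult", "trajectory_fit"]


@dataclass
class TrajectoryFitResult:
    """Best multistart fit with covariance and integration accounting."""

    beta_hat: np.ndarray
    C: np.ndarray
    n_starts: int
    best_objective: float
    n_integrations: int


def _default_center(model: ODEModel, smoothing: CellSmoothing | None, meas) -> np.ndarray:
    if smoothing is not None and meas is not None and hasattr(model, "gmat"):
        from .hidden import default_initial_guess

        return np.abs(default_initial_guess(model, smoothing, meas)) + 1e-12
    return np.ones(model.P)


def trajectory_fit(
    cell: CellMeasurements,
    model: ODEModel,
    noise: list[NoiseEstimate] | None = None,
    measurement: MeasurementModel | None = None,
    smoothing: CellSmoothing | None = None,
    n_starts: int = 10,
    rng: int | np.random.Generator = 0,
    spread: float = 10.0,
    rtol: float = 1e-6,
    max_nfev: int = 200,
) -> TrajectoryFitResult:
    """Weighted multistart nonlinear least squares against ODE solutions.

    Minimizes ``sum_jk (y_jk - [Q x(t_j; beta)]_k)^2 / (sigma_k^2 + tau_k^2
    x_k^2)`` with a derivative-based trust-region solver.  Starting points
    are log-uniform draws within ``[center/spread, center*spread]`` around a
    data-informed center (the restricted gradient-matching guess when
    smoothing output is supplied).  The covariance is the Gauss-Newton
    ``(J'WJ)^-1`` at the best optimum; every ODE integration is counted.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if measurement is None:
        obs = np.arange(cell.K_obs)
        measurement = MeasurementModel.select(model.K, obs, sigma=0.0, tau=0.0)
    Q = measurement.Q
    if noise is not None:
        var = np.column_stack(
            [_weight_floor(noise[k].variance(cell.y[:, k])) for k in range(cell.K_obs)]
        )
    else:
        var = np.ones_like(cell.y)
    w_sqrt = 1.0 / np.sqrt(var)

    counter = {"n": 0}

    def residuals(beta):
        counter["n"] += 1
        try:
            traj = simulate_individual(model, beta, cell.t, rtol=rtol, atol=rtol * 1e-2)
        except IntegrationError:
            return np.full(cell.y.size, 1e6)
        return ((traj @ Q.T - cell.y) * w_sqrt).ravel()

    center = _default_center(model, smoothing, measurement)
    center = np.maximum(np.abs(center), 1e-8)
    log_c = np.log(center)
    half = np.log(spread)
    starts = [center] + [
        np.exp(log_c + rng.uniform(-half, half, model.P)) for _ in range(n_starts - 1)
    ]

    best = None
    for s in starts:
        try:
            sol = least_squares(residuals, s, method="lm", max_nfev=max_nfev)
        except Exception:  # noqa: BLE001 - a failed start is simply skipped
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"trajectory matching failed from all {n_starts} starts "
            f"for cell {cell.cell_id!r}"
        )
    J = best.jac
    JtJ = J.T @ J
    try:
        C = np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        C = np.linalg.pinv(JtJ)
    C = 0.5 * (C + C.T)
    return TrajectoryFitResult(
        beta_hat=best.x,
        C=C,
        n_starts=n_starts,
        best_objective=float(2 * best.cost),
        n_integrations=counter["n"],
    )
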