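"""Penalized cubic B-spline smoothing of single-cell time series.

Gradient matching replaces ODE integration with data-derived time
derivatives, so each measured state is smoothed with a penalized cubic
B-spline and differentiated analytically.  Alongside the state and gradient
estimates, this module produces the spline-coefficient covariance (needed for
uncertainty propagation into the regression residuals) and method-of-moments
estimates of the additive/multiplicative measurement-noise parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import nnls

from .models import CellMeasurements

__all__ = [
    "SplineBasis",
    "SplineFit",
    "NoiseEstimate",
    "build_basis",
    "fit_penalized",
    "select_lambda",
    "estimate_noise",
    "auto_knots",
    "smooth_cell",
    "CellSmoothing",
]

_DEGREE = 3
_LAMBDA_GRID = np.logspace(-6, 3, 40)


@dataclass
class SplineBasis:
    """Cubic B-spline basis evaluated on a fixed data grid.

    ``knots`` are the breakpoints (including both endpoints, clamped with
    full multiplicity); ``B`` and ``Bdot`` evaluate the basis and its first
    derivative at the grid points; ``penalty`` is the exact integrated
    squared-second-derivative roughness matrix.
    """

    knots: np.ndarray
    tgrid: np.ndarray
    B: np.ndarray
    Bdot: np.ndarray
    penalty: np.ndarray
    _spline: BSpline = field(repr=False, default=None)

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    def design(self, t: np.ndarray, deriv: int = 0) -> np.ndarray:
        """Evaluate the (derivative) basis at arbitrary times."""
        s = self._spline if deriv == 0 else self._spline.derivative(deriv)
        return np.asarray(s(np.asarray(t, float)))


def build_basis(knots: np.ndarray, tgrid: np.ndarray) -> SplineBasis:
    """Construct a clamped cubic basis with the given interior breakpoints.

    ``knots`` must lie inside the data range and include the endpoints (they
    are added if absent).  The roughness penalty is computed exactly with
    two-point Gauss-Legendre quadrature per inter-knot interval (the
    integrand is piecewise quadratic for cubic splines).
    """
    tgrid = np.asarray(tgrid, float)
    knots = np.unique(np.concatenate([[tgrid[0], tgrid[-1]], np.asarray(knots, float)]))
    if knots[0] < tgrid[0] or knots[-1] > tgrid[-1]:
        raise ValueError("knots must lie within the data time range")
    n_basis = len(knots) - 2 + _DEGREE + 1
    if n_basis > len(tgrid):
        raise ValueError(
            f"{n_basis} basis functions exceed the {len(tgrid)} data points; "
            "use fewer knots"
        )
    tk = np.concatenate([[knots[0]] * _DEGREE, knots, [knots[-1]] * _DEGREE])
    spline = BSpline(tk, np.eye(n_basis), _DEGREE, extrapolate=False)
    B = np.nan_to_num(np.asarray(spline(tgrid)))
    Bdot = np.nan_to_num(np.asarray(spline.derivative()(tgrid)))

    d2 = spline.derivative(2)
    # 2-point Gauss-Legendre per breakpoint interval: exact for the
    # piecewise-quadratic integrand (d2 B_i)(d2 B_j).
    gl_x = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    pen = np.zeros((n_basis, n_basis))
    for a, b in zip(knots[:-1], knots[1:]):
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        pts = mid + half * gl_x
        D = np.asarray(d2(pts))
        pen += half * (D.T @ D)  # both GL weights are 1
    return SplineBasis(knots=knots, tgrid=tgrid, B=B, Bdot=Bdot, penalty=pen, _spline=spline)


@dataclass
class SplineFit:
    """Penalized-spline fit of one observed state."""

    basis: SplineBasis
    coef: np.ndarray
    coef_cov: np.ndarray
    lam: float
    fitted: np.ndarray
    fitted_deriv: np.ndarray
    edf: float
    leverage: np.ndarray | None = None

    def __call__(self, t: np.ndarray, deriv: int = 0) -> np.ndarray:
        return self.basis.design(t, deriv) @ self.coef


@dataclass
class NoiseEstimate:
    """Estimated additive SD and multiplicative factor of one state."""

    sigma_hat: float
    tau_hat: float

    def variance(self, x: np.ndarray) -> np.ndarray:
        return self.sigma_hat**2 + self.tau_hat**2 * np.asarray(x, float) ** 2


def _normal_matrix(basis: SplineBasis, weights: np.ndarray, lam: float) -> np.ndarray:
    BW = basis.B * weights[:, None]
    return basis.B.T @ BW, BW  # (B'WB, W B) reused by callers


def fit_penalized(
    y: np.ndarray,
    basis: SplineBasis,
    weights: np.ndarray | None = None,
    lam: float = 0.0,
    y_var: np.ndarray | None = None,
) -> SplineFit:
    """Weighted penalized least-squares spline fit of a single state.

    Solves ``(B'WB + lam * P) c = B'W y``.  The coefficient covariance is the
    sandwich ``A^-1 B'W Sigma_y W B A^-1`` with ``Sigma_y = diag(y_var)``
    (defaulting to ``1/weights``, the usual inverse-variance weighting).
    """
    y = np.asarray(y, float)
    T = len(y)
    weights = np.ones(T) if weights is None else np.asarray(weights, float)
    if np.any(weights <= 0):
        raise ValueError("weights must be strictly positive")
    BtWB, BW = _normal_matrix(basis, weights, lam)
    A = BtWB + lam * basis.penalty
    try:
        cf = cho_factor(A)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular penalized normal matrix; use fewer knots or a larger lambda"
        ) from e
    coef = cho_solve(cf, BW.T @ y)
    Ainv_BtW = cho_solve(cf, BW.T)  # A^-1 B'W
    leverage = np.einsum("ij,ji->i", basis.B, Ainv_BtW)  # diag of the smoother
    edf = float(leverage.sum())
    y_var = 1.0 / weights if y_var is None else np.asarray(y_var, float)
    cov = (Ainv_BtW * y_var) @ Ainv_BtW.T
    cov = 0.5 * (cov + cov.T)
    return SplineFit(
        basis=basis,
        coef=coef,
        coef_cov=cov,
        lam=float(lam),
        fitted=basis.B @ coef,
        fitted_deriv=basis.Bdot @ coef,
        edf=edf,
        leverage=leverage,
    )


def select_lambda(
    y: np.ndarray,
    basis: SplineBasis,
    weights: np.ndarray | None = None,
    grid: np.ndarray = _LAMBDA_GRID,
) -> float:
    """Pick the roughness penalty by generalized cross-validation.

    GCV(lam) = T * RSS(lam) / (T - edf(lam))^2 minimized over a log-spaced
    grid; entirely deterministic.  The whole scan costs one generalized
    eigendecomposition of (penalty, B'WB): in the rotated basis the
    weighted RSS and the effective degrees of freedom are O(n_basis) per
    grid point.
    """
    y = np.asarray(y, float)
    T = len(y)
    weights = np.ones(T) if weights is None else np.asarray(weights, float)
    BtWB, BW = _normal_matrix(basis, weights, 0.0)
    rhs = BW.T @ y
    try:
        from scipy.linalg import eigh

        gamma, U = eigh(basis.penalty, BtWB)  # U' BtWB U = I, U' P U = diag
    except np.linalg.LinAlgError:  # pragma: no cover - ill-posed basis
        gamma = None
    if gamma is None:
        best_lam, best_score = float(grid[0]), np.inf
        for lam in grid:
            fit = fit_penalized(y, basis, weights, lam)
            rss = float(np.sum(weights * (y - fit.fitted) ** 2))
            score = T * rss / max(T - fit.edf, 1e-8) ** 2
            if score < best_score:
                best_lam, best_score = float(lam), score
        return best_lam
    gamma = np.clip(gamma, 0.0, None)
    z = U.T @ rhs
    yWy = float(np.sum(weights * y * y))
    best_lam, best_score = float(grid[0]), np.inf
    for lam in grid:
        shrink = 1.0 / (1.0 + lam * gamma)
        zs = z * shrink
        rss = yWy - 2.0 * float(z @ zs) + float(zs @ zs)
        edf = float(shrink.sum())
        score = T * max(rss, 0.0) / max(T - edf, 1e-8) ** 2
        if score < best_score:
            best_lam, best_score = float(lam), score
    return best_lam


def estimate_noise(y: np.ndarray, fit: SplineFit) -> NoiseEstimate:
    """Method-of-moments noise estimate from smoother residuals.

    Squared residuals, corrected pointwise by the smoother leverage 1/(1 - h_jj)
    for the degrees of freedom absorbed by the smoother, are regressed on (1, xhat^2) under
    nonnegativity constraints; the intercept estimates sigma^2 and the slope
    tau^2.
    """
    y = np.asarray(y, float)
    T = len(y)
    if T < 5:
        raise ValueError("need at least 5 time points to estimate noise")
    r2 = (y - fit.fitted) ** 2
    if fit.leverage is not None:
        r2 = r2 / np.clip(1.0 - fit.leverage, 0.05, 1.0)
    else:
        r2 = r2 * T / max(T - fit.edf, 1.0)
    x2 = fit.fitted**2
    mean_x2 = float(np.mean(x2))
    spread = float(np.std(x2)) / max(mean_x2, 1e-300)
    if spread < 0.1 and mean_x2 > 0:
        # x^2 is (nearly) constant, so the additive/multiplicative split is
        # unidentifiable; attribute the variance to the multiplicative term,
        # the dominant noise mode in fluorescence-type measurements.
        return NoiseEstimate(sigma_hat=0.0, tau_hat=float(np.sqrt(np.mean(r2) / mean_x2)))
    X = np.column_stack([np.ones(T), x2])
    coefs, _ = nnls(X, r2)
    return NoiseEstimate(sigma_hat=float(np.sqrt(coefs[0])), tau_hat=float(np.sqrt(coefs[1])))


def auto_knots(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Feature-based interior-knot placement heuristic.

    The series is pre-smoothed with a moving average (window ~T/10), then
    interior knots are placed at local extrema and inflection candidates of
    the pre-smoothed curve.  Knots closer than two median time steps are
    merged, endpoints are always included, and the count is capped at T/2.
    Deterministic in its inputs.
    """
    y = np.asarray(y, float)
    t = np.asarray(t, float)
    T = len(y)
    if T < 5:
        raise ValueError("need at least 5 time points")
    w = max(int(np.ceil(T / 10)), 1)
    kernel = np.ones(w) / w
    ys = np.convolve(np.pad(y, (w // 2, w - 1 - w // 2), mode="edge"), kernel, "valid")

    d1 = np.gradient(ys, t)
    d2 = np.gradient(d1, t)
    cand = set()
    for s in (d1, d2):  # sign changes mark extrema / inflections
        sign = np.sign(s)
        idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        cand.update((idx + 1).tolist())
    cand = sorted(cand)

    dt_med = float(np.median(np.diff(t)))
    interior: list[float] = []
    for i in cand:
        ti = t[i]
        if ti <= t[0] + dt_med or ti >= t[-1] - dt_med:
            continue
        if interior and ti - interior[-1] < 2 * dt_med:
            continue
        interior.append(float(ti))
    max_interior = T // 2
    if len(interior) > max_interior:
        pick = np.linspace(0, len(interior) - 1, max_interior).round().astype(int)
        interior = [interior[i] for i in pick]
    return np.concatenate([[t[0]], interior, [t[-1]]])


def _default_knots(t: np.ndarray) -> np.ndarray:
    """Generous equally spaced knots; the roughness penalty controls wiggliness.

    This is the usual penalized-spline recipe: rather than hand-placing a few
    knots, use a moderately rich uniform grid and let GCV choose the penalty.
    """
    n_interior = int(np.clip(len(t) // 2, 4, 20))
    return np.linspace(t[0], t[-1], n_interior + 2)


@dataclass
class CellSmoothing:
    """Per-state spline fits and noise estimates of one cell."""

    fits: list[SplineFit]
    noise: list[NoiseEstimate]
    n_rounds: int

    @property
    def xhat(self) -> np.ndarray:
        return np.column_stack([f.fitted for f in self.fits])

    @property
    def xdot_hat(self) -> np.ndarray:
        return np.column_stack([f.fitted_deriv for f in self.fits])


def _weight_floor(var: np.ndarray) -> np.ndarray:
    """Floor the variance so weights stay finite where the signal vanishes."""
    v = np.asarray(var, float)
    floor = max(1e-4 * float(np.max(v, initial=0.0)), 1e-12)
    return np.maximum(v, floor)


def smooth_cell(
    cell: CellMeasurements,
    knots: list[np.ndarray] | np.ndarray | None = None,
    lam: list[float] | float | None = None,
    max_rounds: int = 5,
    rel_tol: float = 0.01,
    noise_override: list[NoiseEstimate] | None = None,
) -> CellSmoothing:
    """Smooth all observed states of one cell with noise-adaptive weights.

    Each state is fitted, its noise parameters are estimated from the
    residuals, and the fit is repeated with weights 1/(sigma^2 + tau^2 xhat^2)
    until the noise estimates change by less than ``rel_tol`` (relative) or
    ``max_rounds`` rounds have run.  Knots and lambda may be supplied
    per-state or shared; by default knots form a moderately rich uniform grid
    and lambda is chosen by GCV (the feature heuristic ``auto_knots`` is
    available as an alternative knot source).
    """
    Kobs = cell.K_obs
    if knots is None:
        knot_list = [None] * Kobs
    elif isinstance(knots, np.ndarray):
        knot_list = [knots] * Kobs
    else:
        knot_list = list(knots)
    if lam is None or np.isscalar(lam):
        lam_list = [lam] * Kobs
    else:
        lam_list = list(lam)

    fits: list[SplineFit] = []
    noises: list[NoiseEstimate] = []
    rounds_used = 1
    for k in range(Kobs):
        y = cell.y[:, k]
        kn = knot_list[k]
        if kn is None:
            kn = _default_knots(cell.t)
        basis = build_basis(kn, cell.t)
        lam_user = lam_list[k]
        if noise_override is not None:
            # fixed (e.g. population-pooled) noise model: two weighted passes,
            # the second with weights from the first pass's fitted values
            noise = noise_override[k]
            var = _weight_floor(noise.variance(y))
            lam_k = select_lambda(y, basis, 1.0 / var) if lam_user is None else lam_user
            fit = fit_penalized(y, basis, 1.0 / var, lam_k, y_var=var)
            var = _weight_floor(noise.variance(fit.fitted))
            if lam_user is None:
                lam_k = select_lambda(y, basis, 1.0 / var)
            fit = fit_penalized(y, basis, 1.0 / var, lam_k, y_var=var)
            fits.append(fit)
            noises.append(noise)
            continue
        weights = np.ones(cell.T)
        # lambda is re-selected whenever the weights change: rescaling W
        # rescales B'WB against the fixed penalty, so a lambda tuned under
        # unit weights is badly calibrated for inverse-variance weights.
        lam_k = select_lambda(y, basis, weights) if lam_user is None else lam_user
        fit = fit_penalized(y, basis, weights, lam_k)
        noise = estimate_noise(y, fit)
        for r in range(2, max_rounds + 1):
            var = _weight_floor(noise.variance(fit.fitted))
            weights = 1.0 / var
            if lam_user is None:
                lam_k = select_lambda(y, basis, weights)
            fit = fit_penalized(y, basis, weights, lam_k, y_var=var)
            new_noise = estimate_noise(y, fit)
            prev = np.array([noise.sigma_hat, noise.tau_hat])
            cur = np.array([new_noise.sigma_hat, new_noise.tau_hat])
            noise = new_noise
            rounds_used = max(rounds_used, r)
            denom = np.maximum(np.abs(prev), 1e-12)
            if np.all(np.abs(cur - prev) / denom < rel_tol):
                break
        # final fit with converged weights so coef_cov reflects them
        var = _weight_floor(noise.variance(fit.fitted))
        fit = fit_penalized(y, basis, 1.0 / var, lam_k, y_var=var)
        fits.append(fit)
        noises.append(noise)
    return CellSmoothing(fits=fits, noise=noises, n_rounds=rounds_used)
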