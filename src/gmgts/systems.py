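"""Builtin example systems: generalized Lotka-Volterra, repressilator, and
fluorescent-protein maturation kinetics.

All factories return models whose right-hand side is linear in the free
parameters (the Hill-form repressilator being the deliberate exception, kept
for simulation and trajectory matching only).
"""

from __future__ import annotations

import numpy as np

from .models import LinearODEModel, ODEModel

__all__ = [
    "make_lotka_volterra",
    "make_repressilator",
    "make_fp_maturation",
    "repressilator_qssa_occupancy",
]

# Repressilator rate constants (concentrations in uM, time in min):
# basal transcription 5e-4, maximal regulated transcription 0.5, mRNA
# degradation+dilution 0.3466, translation 20; repression follows a Hill
# function with squared-protein binding scaled by 2.5e-4.
_REP_BASAL = 0.0005
_REP_VMAX = 0.5
_REP_MDEG = 0.3466
_REP_TRANSL = 20.0
_REP_BIND = 0.00025
# Each gene n is repressed by the protein of gene rep[n].
_REP_PAIRING = (2, 0, 1)  # (n1, n2) = (1,3), (2,1), (3,2) in 1-based indexing


def make_lotka_volterra(m: int = 4) -> LinearODEModel:
    """Generalized Lotka-Volterra ring with 16 species and m free rates.

    State n grows at fixed rate r_n = n/80 and is inhibited by the next
    species in the ring: ``xdot_n = x_n (r_n - k_n x_{n+1})`` (cyclically).
    The interaction rates are tied as k_{n1} = k_{n2} whenever
    ``n1 == n2 (mod m)``, leaving ``m`` distinct free parameters.
    """
    K = 16
    if m < 1 or K % m != 0:
        raise ValueError(f"m={m} must divide {K}")
    r = np.arange(1, K + 1) / 80.0
    nxt = np.roll(np.arange(K), -1)  # species inhibiting each state
    col = np.arange(K) % m  # tied-parameter column for each state

    def g(x):
        G = np.zeros((K, m))
        G[np.arange(K), col] = -x * x[nxt]
        return G

    def h(x):
        return r * x

    def jac_x(x, beta):
        k = beta[col]
        J = np.zeros((K, K))
        J[np.arange(K), np.arange(K)] = r - k * x[nxt]
        J[np.arange(K), nxt] += -k * x
        return J

    return LinearODEModel(
        K=K,
        P=m,
        state_names=[f"x{n}" for n in range(1, K + 1)],
        param_names=[f"k{j}" for j in range(1, m + 1)],
        x0=np.ones(K),
        g=g,
        h=h,
        fixed_params={"r": r.tolist()},
        jac_x=jac_x,
        name=f"lotka_volterra_m{m}",
    )


def repressilator_qssa_occupancy(p_repressor: float, alpha: float) -> float:
    """Quasi-steady-state promoter occupancy for a given repressor level."""
    s = _REP_BIND * p_repressor**2
    return s / (alpha + s)


def _repressilator_x0(kappa_unused=None, alpha_nominal: float = 0.16):
    m0 = 0.01 * np.arange(1, 4)
    p0 = 0.1 * np.arange(1, 4)
    c0 = np.array(
        [repressilator_qssa_occupancy(p0[_REP_PAIRING[n]], alpha_nominal) for n in range(3)]
    )
    return m0, p0, c0


def make_repressilator(
    expanded: bool = True, kappa: float = 10.0, x0_mode: str = "attractor"
) -> ODEModel:
    """Three-gene repressilator; Hill form or mass-action expansion.

    With ``expanded=False`` the classic six-state Hill-kinetics model is
    returned; its repression terms are nonlinear in the promoter-affinity
    parameters alpha_n, so it supports simulation and trajectory matching
    only.  With ``expanded=True`` one promoter-occupancy state ``c_n`` per
    gene is added, turning repression into mass-action binding kinetics with
    time-scale constant ``kappa`` (1/min):

        cdot_n = kappa * (0.00025 p_{rep(n)}^2 (1 - c_n) - alpha_n c_n)
        mdot_n = 0.0005 + 0.5 (1 - c_n) - 0.3466 m_n
        pdot_n = 20 m_n - beta_n p_n

    The expanded system is linear in (alpha_1..3, beta_1..3) and its
    quasi-steady-state limit (kappa -> inf) recovers the Hill form.

    ``x0_mode`` selects the known initial condition: ``"attractor"``
    (default) places the system on its limit cycle by a 400-min burn-in at
    the nominal parameters, emulating cells observed in steady oscillation;
    ``"startup"`` uses low initial mRNA/protein levels, which produces a
    fast induction transient.
    """
    if x0_mode not in ("attractor", "startup"):
        raise ValueError("x0_mode must be 'attractor' or 'startup'")
    m0, p0, c0 = _repressilator_x0()
    param_names = ["alpha1", "alpha2", "alpha3", "beta1", "beta2", "beta3"]

    if not expanded:
        state_names = ["m1", "p1", "m2", "p2", "m3", "p3"]
        x0 = np.empty(6)
        x0[0::2], x0[1::2] = m0, p0

        def f(x, beta):
            mm, pp = x[0::2], x[1::2]
            alpha, bdeg = beta[:3], beta[3:]
            prep = pp[list(_REP_PAIRING)]
            mdot = (
                _REP_BASAL
                + _REP_VMAX * alpha / (alpha + _REP_BIND * prep**2)
                - _REP_MDEG * mm
            )
            pdot = _REP_TRANSL * mm - bdeg * pp
            out = np.empty(6)
            out[0::2], out[1::2] = mdot, pdot
            return out

        model = ODEModel(
            K=6,
            P=6,
            state_names=state_names,
            param_names=param_names,
            x0=x0,
            f=f,
            fixed_params={"hill_scale": _REP_BIND},
            name="repressilator_hill",
        )
        return _settle_repressilator(model, x0_mode)

    # Expanded model: states (m1, p1, m2, p2, m3, p3, c1, c2, c3)
    state_names = ["m1", "p1", "m2", "p2", "m3", "p3", "c1", "c2", "c3"]
    x0 = np.empty(9)
    x0[0:6:2], x0[1:6:2], x0[6:] = m0, p0, c0
    K, P = 9, 6

    def g(x):
        pp, cc = x[1:6:2], x[6:]
        G = np.zeros((K, P))
        for n in range(3):
            G[1 + 2 * n, 3 + n] = -pp[n]  # beta_n in pdot_n
            G[6 + n, n] = -kappa * cc[n]  # alpha_n in cdot_n
        return G

    def h(x):
        mm, pp, cc = x[0:6:2], x[1:6:2], x[6:]
        prep = pp[list(_REP_PAIRING)]
        out = np.empty(K)
        out[0:6:2] = _REP_BASAL + _REP_VMAX * (1 - cc) - _REP_MDEG * mm
        out[1:6:2] = _REP_TRANSL * mm
        out[6:] = kappa * _REP_BIND * prep**2 * (1 - cc)
        return out

    def jac_x(x, beta):
        pp, cc = x[1:6:2], x[6:]
        alpha, bdeg = beta[:3], beta[3:]
        J = np.zeros((K, K))
        for n in range(3):
            im, ip, ic = 2 * n, 1 + 2 * n, 6 + n
            iprep = 1 + 2 * _REP_PAIRING[n]
            J[im, im] = -_REP_MDEG
            J[im, ic] = -_REP_VMAX
            J[ip, im] = _REP_TRANSL
            J[ip, ip] = -bdeg[n]
            J[ic, iprep] = kappa * _REP_BIND * 2 * pp[_REP_PAIRING[n]] * (1 - cc[n])
            J[ic, ic] = -kappa * (_REP_BIND * pp[_REP_PAIRING[n]] ** 2 + alpha[n])
        return J

    model = LinearODEModel(
        K=K,
        P=P,
        state_names=state_names,
        param_names=param_names,
        x0=x0,
        g=g,
        h=h,
        fixed_params={"kappa": kappa},
        jac_x=jac_x,
        name="repressilator_expanded",
    )
    return _settle_repressilator(model, x0_mode)


_REP_NOMINAL = np.array([0.16, 0.16, 0.16, 0.0693, 0.0693, 0.0693])


def _settle_repressilator(model: ODEModel, x0_mode: str, burn_in: float = 400.0):
    """Replace x0 by the state after a burn-in at the nominal parameters.

    Puts the known initial condition on the limit cycle so that simulated
    measurement windows start in steady oscillation rather than in the fast
    induction transient, which is not resolvable at the study's 5-min
    sampling interval.
    """
    if x0_mode == "startup":
        return model
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, x: model.rhs(x, _REP_NOMINAL),
        (0.0, burn_in),
        model.x0,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    model.x0 = sol.y[:, -1].copy()
    return model


def make_fp_maturation(
    steps: int = 1,
    k_r: float = 0.1,
    k_dr: float = 0.07,
    k_dil: float = 0.004,
) -> LinearODEModel:
    """Fluorescent-protein expression and maturation kinetics.

    Transcription switches on at t = 0 with fixed rate ``k_r``
    (transcripts/min); mRNA (M) decays at ``k_dr`` and every species is
    diluted by growth at ``k_dil`` (1/min).  Dark protein is translated at
    rate ``k_p`` and matures into fluorescent protein F at rate ``k_m`` —
    directly (one step) or via a nonfluorescent intermediate D2 with the same
    rate for both transitions (two steps).  Free parameters: (k_p, k_m).
    All initial conditions are zero.
    """
    if steps not in (1, 2):
        raise ValueError("steps must be 1 or 2")
    fixed = {"k_r": k_r, "k_dr": k_dr, "k_dil": k_dil}
    param_names = ["k_p", "k_m"]

    if steps == 1:
        K = 3
        state_names = ["M", "D", "F"]

        def g(x):
            M, D, F = x
            return np.array([[0.0, 0.0], [M, -D], [0.0, D]])

        def h(x):
            M, D, F = x
            return np.array([k_r - (k_dr + k_dil) * M, -k_dil * D, -k_dil * F])

        def jac_x(x, beta):
            k_p, k_m = beta
            return np.array(
                [
                    [-(k_dr + k_dil), 0.0, 0.0],
                    [k_p, -(k_m + k_dil), 0.0],
                    [0.0, k_m, -k_dil],
                ]
            )

    else:
        K = 4
        state_names = ["M", "D1", "D2", "F"]

        def g(x):
            M, D1, D2, F = x
            return np.array(
                [[0.0, 0.0], [M, -D1], [0.0, D1 - D2], [0.0, D2]]
            )

        def h(x):
            M, D1, D2, F = x
            return np.array(
                [k_r - (k_dr + k_dil) * M, -k_dil * D1, -k_dil * D2, -k_dil * F]
            )

        def jac_x(x, beta):
            k_p, k_m = beta
            return np.array(
                [
                    [-(k_dr + k_dil), 0.0, 0.0, 0.0],
                    [k_p, -(k_m + k_dil), 0.0, 0.0],
                    [0.0, k_m, -(k_m + k_dil), 0.0],
                    [0.0, 0.0, k_m, -k_dil],
                ]
            )

    return LinearODEModel(
        K=K,
        P=2,
        state_names=state_names,
        param_names=param_names,
        x0=np.zeros(K),
        g=g,
        h=h,
        fixed_params=fixed,
        jac_x=jac_x,
        name=f"fp_maturation_{steps}step",
    )
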