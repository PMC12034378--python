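"""Synthetic-data scenarios for the builtin study systems.

Each scenario samples cell-specific parameters from a population
distribution, integrates the individual ODEs with tight tolerances, and adds
heteroscedastic measurement noise.  Defaults match the published simulation
settings of the respective study systems; every setting can be overridden.
"""

from __future__ import annotations

import numpy as np

from .models import (
    CellMeasurements,
    MeasurementModel,
    PopulationDataset,
    PopulationDistribution,
    observe,
    sample_parameters,
    simulate_individual,
)
from .systems import make_fp_maturation, make_lotka_volterra, make_repressilator

__all__ = ["SCENARIOS", "generate_scenario"]


def _lv_defaults(partial: bool) -> dict:
    return dict(
        m=4,
        N=100,
        tgrid=np.arange(0.0, 21.0),
        tau=0.05,
        sigma=0.0,
        mean=0.02,
        sd=0.005,
        hidden_states=list(range(4)) if partial else [],
        family="normal",
    )


def _repressilator_defaults() -> dict:
    return dict(
        N=100,
        tgrid=np.arange(0.0, 101.0, 5.0),
        tau=0.05,
        sigma=0.0,
        alpha_mean=0.16,
        beta_mean=0.0693,
        cv=0.1,
        rho=0.5,
        kappa=10.0,
        family="normal",
    )


def _fp_defaults(steps: int) -> dict:
    return dict(
        steps=steps,
        N=500,
        tgrid=np.arange(0.0, 201.0, 5.0),
        tau=0.05,
        sigma=0.0,
        kp_mean=0.025,
        km_mean=0.05,
        cv=0.25,
        family="normal",
    )


SCENARIOS = (
    "lotka_volterra_full",
    "lotka_volterra_partial",
    "repressilator",
    "fp_one_step",
    "fp_two_step",
)


def _build(name: str, settings: dict):
    if name.startswith("lotka_volterra"):
        model = make_lotka_volterra(settings["m"])
        P = model.P
        dist = PopulationDistribution(
            settings["family"],
            np.full(P, settings["mean"]),
            np.eye(P) * settings["sd"] ** 2,
        )
        observed = [k for k in range(model.K) if k not in settings["hidden_states"]]
        meas = MeasurementModel.select(
            model.K, observed, sigma=settings["sigma"], tau=settings["tau"]
        )
    elif name == "repressilator":
        model = make_repressilator(expanded=True, kappa=settings["kappa"])
        am, bm, cv, rho = (
            settings["alpha_mean"],
            settings["beta_mean"],
            settings["cv"],
            settings["rho"],
        )
        b = np.array([am] * 3 + [bm] * 3)
        sd = cv * b
        D = np.diag(sd**2)
        for n in range(3):  # correlation within each (alpha_n, beta_n) pair
            D[n, 3 + n] = D[3 + n, n] = rho * sd[n] * sd[3 + n]
        dist = PopulationDistribution(settings["family"], b, D)
        meas = MeasurementModel.select(
            model.K, list(range(6)), sigma=settings["sigma"], tau=settings["tau"]
        )
    elif name.startswith("fp_"):
        model = make_fp_maturation(settings["steps"])
        b = np.array([settings["kp_mean"], settings["km_mean"]])
        D = np.diag((settings["cv"] * b) ** 2)
        dist = PopulationDistribution(settings["family"], b, D)
        meas = MeasurementModel.select(
            model.K, [model.K - 1], sigma=settings["sigma"], tau=settings["tau"]
        )  # only mature fluorescent protein is measured
    else:  # pragma: no cover - guarded by generate_scenario
        raise ValueError(name)
    return model, dist, meas


def generate_scenario(
    name: str, overrides: dict | None = None, seed: int = 0
) -> PopulationDataset:
    """Generate a full synthetic dataset for a named scenario.

    Valid names: ``lotka_volterra_full``, ``lotka_volterra_partial``,
    ``repressilator``, ``fp_one_step``, ``fp_two_step``.  ``overrides``
    replaces any default setting (N, tgrid, tau, sigma, population moments,
    ...).  All randomness derives from ``seed``; ground-truth parameter
    vectors are stored on each cell.
    """
    if name == "lotka_volterra_full":
        settings = _lv_defaults(partial=False)
    elif name == "lotka_volterra_partial":
        settings = _lv_defaults(partial=True)
    elif name == "repressilator":
        settings = _repressilator_defaults()
    elif name == "fp_one_step":
        settings = _fp_defaults(1)
    elif name == "fp_two_step":
        settings = _fp_defaults(2)
    else:
        raise ValueError(
            f"unknown scenario {name!r}; valid scenarios: {', '.join(SCENARIOS)}"
        )
    if overrides:
        unknown = set(overrides) - set(settings)
        if unknown:
            raise ValueError(f"unknown override keys: {sorted(unknown)}")
        settings.update(overrides)

    model, dist, meas = _build(name, settings)
    tgrid = np.asarray(settings["tgrid"], float)
    N = int(settings["N"])
    rng = np.random.default_rng(seed)
    betas = sample_parameters(dist, N, rng)

    cells = []
    for i in range(N):
        traj = simulate_individual(model, betas[i], tgrid)
        y = observe(traj, meas, rng)
        cells.append(
            CellMeasurements(cell_id=f"cell{i:04d}", t=tgrid, y=y, true_beta=betas[i])
        )
    return PopulationDataset(
        cells=cells,
        model=model,
        measurement=meas,
        generating_distribution=dist,
        seed=seed,
        scenario=name,
    )
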