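"""Dataset and estimate round-tripping.

Datasets are stored as long-format CSV (cell_id, time, state_name, value)
with a JSON sidecar carrying everything the CSV cannot: the model name and
its factory arguments, fixed parameters, the selection matrix, the seed,
and — for simulated data — the generating distribution and ground-truth
parameter vectors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .em import PopulationEstimate
from .gls import IndividualEstimate
from .models import (
    CellMeasurements,
    MeasurementModel,
    ODEModel,
    PopulationDataset,
    PopulationDistribution,
)
from .systems import make_fp_maturation, make_lotka_volterra, make_repressilator

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_individual_estimates",
    "read_individual_estimates",
    "write_population_estimate",
    "read_population_estimate",
]

# registry of model factories for sidecar-driven reconstruction
_FACTORIES = {
    "lotka_volterra": make_lotka_volterra,
    "repressilator": make_repressilator,
    "fp_maturation": make_fp_maturation,
}


def model_reference(model: ODEModel) -> dict:
    """A serializable reference to a builtin model (factory + arguments)."""
    name = model.name
    if name.startswith("lotka_volterra_m"):
        return {"factory": "lotka_volterra", "args": {"m": model.P}}
    if name == "repressilator_hill":
        return {"factory": "repressilator", "args": {"expanded": False}}
    if name == "repressilator_expanded":
        return {
            "factory": "repressilator",
            "args": {"expanded": True, "kappa": model.fixed_params.get("kappa", 10.0)},
        }
    if name.startswith("fp_maturation"):
        steps = 1 if "1step" in name else 2
        return {"factory": "fp_maturation", "args": {"steps": steps, **model.fixed_params}}
    raise ValueError(
        f"model {name!r} is not a builtin; datasets with custom models must be "
        "reconstructed in memory"
    )


def _model_from_reference(ref: dict) -> ODEModel:
    return _FACTORIES[ref["factory"]](**ref["args"])


def write_dataset(dataset: PopulationDataset, path: str | Path) -> None:
    """Write the CSV + JSON sidecar pair; `path` is the CSV file."""
    path = Path(path)
    rows = []
    state_names = [
        dataset.model.state_names[k] for k in dataset.measurement.observed_indices
    ]
    for cell in dataset.cells:
        for j, t in enumerate(cell.t):
            for k, name in enumerate(state_names):
                rows.append((cell.cell_id, t, name, cell.y[j, k]))
    pd.DataFrame(rows, columns=["cell_id", "time", "state_name", "value"]).to_csv(
        path, index=False
    )
    meta = {
        "model": model_reference(dataset.model),
        "fixed_params": dataset.model.fixed_params,
        "Q": dataset.measurement.Q.tolist(),
        "sigma": dataset.measurement.sigma.tolist(),
        "tau": dataset.measurement.tau.tolist(),
        "seed": dataset.seed,
        "scenario": dataset.scenario,
    }
    if dataset.generating_distribution is not None:
        d = dataset.generating_distribution
        meta["generating_distribution"] = {
            "family": d.family,
            "b": d.b.tolist(),
            "D": d.D.tolist(),
        }
    if dataset.true_betas is not None:
        meta["true_betas"] = {
            c.cell_id: c.true_beta.tolist() for c in dataset.cells
        }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_dataset(path: str | Path) -> PopulationDataset:
    """Rebuild a PopulationDataset from the CSV + sidecar pair."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = _model_from_reference(meta["model"])
    meas = MeasurementModel(
        Q=np.asarray(meta["Q"], float),
        sigma=np.asarray(meta["sigma"], float),
        tau=np.asarray(meta["tau"], float),
    )
    df = pd.read_csv(path)
    state_names = [model.state_names[k] for k in meas.observed_indices]
    true_betas = meta.get("true_betas", {})
    cells = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        wide = group.pivot(index="time", columns="state_name", values="value")
        wide = wide.sort_index()[state_names]
        cells.append(
            CellMeasurements(
                cell_id=str(cell_id),
                t=wide.index.to_numpy(float),
                y=wide.to_numpy(float),
                true_beta=(
                    np.asarray(true_betas[str(cell_id)], float)
                    if str(cell_id) in true_betas
                    else None
                ),
            )
        )
    dist = None
    if "generating_distribution" in meta:
        g = meta["generating_distribution"]
        dist = PopulationDistribution(g["family"], np.asarray(g["b"]), np.asarray(g["D"]))
    return PopulationDataset(
        cells=cells,
        model=model,
        measurement=meas,
        generating_distribution=dist,
        seed=meta.get("seed"),
        scenario=meta.get("scenario"),
    )


def write_individual_estimates(estimates: list[IndividualEstimate], path: str | Path) -> None:
    Path(path).write_text(json.dumps([e.to_dict() for e in estimates], indent=2))


def read_individual_estimates(path: str | Path) -> list[IndividualEstimate]:
    return [IndividualEstimate.from_dict(d) for d in json.loads(Path(path).read_text())]


def write_population_estimate(est: PopulationEstimate, path: str | Path) -> None:
    Path(path).write_text(json.dumps(est.to_dict(), indent=2))


def read_population_estimate(path: str | Path) -> PopulationEstimate:
    return PopulationEstimate.from_dict(json.loads(Path(path).read_text()))
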