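import numpy as np
import pytest

from gmgts import (
    MeasurementModel,
    generate_scenario,
    make_fp_maturation,
    make_lotka_volterra,
    make_repressilator,
    simulate_individual,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def lv_model():
    return make_lotka_volterra(4)


@pytest.fixture(scope="session")
def fp_model():
    return make_fp_maturation(1)


@pytest.fixture(scope="session")
def repressilator_model():
    return make_repressilator(expanded=True)


@pytest.fixture(scope="session")
def lv_cell_noisy():
    """One noisy fully observed Lotka-Volterra cell at the study settings."""
    ds = generate_scenario("lotka_volterra_full", seed=101, overrides={"N": 1})
    return ds.model, ds.measurement, ds.cells[0]


@pytest.fixture(scope="session")
def lv_traj_dense(lv_model):
    """Noiseless dense Lotka-Volterra trajectory at the population mean."""
    beta = np.full(4, 0.02)
    tgrid = np.linspace(0.0, 20.0, 201)
    return beta, tgrid, simulate_individual(lv_model, beta, tgrid)


@pytest.fixture(scope="session")
def fp_dataset_small():
    return generate_scenario("fp_one_step", seed=77, overrides={"N": 12})


@pytest.fixture(scope="session")
def full_measurement():
    def _make(K, sigma=0.0, tau=0.05):
        return MeasurementModel.identity(K, sigma=sigma, tau=tau)

    return _make
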