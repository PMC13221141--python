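import numpy as np
import pytest

from tdtsurv.fluctuating import TemperatureProfile
from tdtsurv.synthetic import SimulationConfig, generate_static_dataset


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=101)


@pytest.fixture(scope="session")
def default_model(default_config):
    """True temperature-linked log-logistic behind the default generator."""
    return default_config.model


@pytest.fixture(scope="session")
def static_sim(default_config):
    """Moderate-size static dataset (8 temperatures x 100 flies)."""
    cfg = SimulationConfig(seed=101, n_per_cell=100)
    return generate_static_dataset(cfg)


@pytest.fixture(scope="session")
def constant_shape_sim():
    """Static dataset whose generating shape does not change with
    temperature (gamma1 = 0, k = 3)."""
    cfg = SimulationConfig(seed=77, n_per_cell=100, gamma0=float(np.log(3.0)), gamma1=0.0)
    return generate_static_dataset(cfg)


@pytest.fixture(scope="session")
def narrow_k3_sim():
    """Single-assay regime: 4 temperatures spanning 3 degC (the span of a
    typical per-species knockdown series), constant shape k = 3, 500
    flies in total."""
    cfg = SimulationConfig(
        seed=77, n_per_cell=125, temperatures=(36.0, 37.0, 38.0, 39.0),
        gamma0=float(np.log(3.0)), gamma1=0.0,
    )
    return generate_static_dataset(cfg)


@pytest.fixture
def step_profile() -> TemperatureProfile:
    return TemperatureProfile.stepwise([60.0, 120.0], [36.0, 39.0])
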