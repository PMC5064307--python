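import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ddplex as dd

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def layout() -> dd.AssayLayout:
    """Illustrative 4-plex layout (endogene + three events, two per channel)."""
    return dd.example_tetraplex()


@pytest.fixture
def quant_config() -> dd.QuantConfig:
    return dd.QuantConfig()


@pytest.fixture
def sim_config(layout) -> dd.SimulationConfig:
    """Default 4-plex well: all targets at 500 copies per reaction, no rain."""
    return dd.SimulationConfig(
        copies_per_reaction={t.name: 500.0 for t in layout.targets}, seed=7
    )


@pytest.fixture
def simulated_well(sim_config, layout):
    return dd.simulate_well(sim_config, layout)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20161014)
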