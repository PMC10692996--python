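import numpy as np
import pytest

from malines.consensus import FilterConfig
from malines.simulate import SimulationConfig, simulate_experiment


@pytest.fixture
def filters():
    return FilterConfig()


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=11,
        genome_length=50_000,
        n_regimes=3,
        lines_per_regime=6,
        mu_per_regime=(3e-6, 1e-6, 4e-6),
        mean_depth_per_regime=(60.0, 70.0, 55.0),
        callable_fraction_target=0.8,
    )


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
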