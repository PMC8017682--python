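import numpy as np
import pytest

from omaccum import ModelConfig, build_specialist_matrix, sample_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_specialist():
    """A 5-pool specialist system with its matrix and parameters."""
    config = ModelConfig(
        n_pools=5,
        n_populations=5,
        total_supply=5e-4,
        t_end=100.0,
        dt=0.01,
        seed=7,
        matrix_mode="specialist",
    )
    matrix = build_specialist_matrix(5)
    params = sample_parameters(config, matrix, np.random.default_rng(7))
    return config, matrix, params
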