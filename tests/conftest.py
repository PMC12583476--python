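import numpy as np
import pytest

from mesbi import (
    ArchConfig,
    FrequencyGrid,
    MiddleEarParams,
    NoiseModel,
    PriorBox,
    build_training_set,
    train_npe,
)
from mesbi.features import default_base_sigma


@pytest.fixture(scope="session")
def prior():
    return PriorBox()


@pytest.fixture(scope="session")
def grid():
    return FrequencyGrid()


@pytest.fixture(scope="session")
def midpoint_params(prior):
    return MiddleEarParams.from_array((prior.low_arr + prior.high_arr) / 2.0)


@pytest.fixture(scope="session")
def base_noise(grid):
    return NoiseModel(sigma=default_base_sigma(grid), scale=1.0)


@pytest.fixture(scope="session")
def tiny_model(prior, base_noise):
    """Small trained posterior for contract tests (not for accuracy checks)."""
    ts = build_training_set(prior, 400, base_noise, seed=5)
    return train_npe(ts, ArchConfig(seed=5, max_epochs=60))
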