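import numpy as np
import pytest

from synergypipe.synthetic_data import (
    SyntheticConfig,
    generate_accel,
    generate_emg,
)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One default synthetic recording with its ground truth."""
    return generate_emg(default_config, seed=1)


@pytest.fixture(scope="session")
def default_accel(default_config):
    return generate_accel(default_config, seed=1)


@pytest.fixture(scope="session")
def clean_config():
    """No jitter, no noise: exactly low-rank data."""
    return SyntheticConfig(
        amplitude_jitter_sd=0.0,
        timing_jitter_sd=0.0,
        noise_sd=0.0,
        cycle_duration_sd_s=0.0,
        accel_noise_sd_g=0.0,
        seed=2,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_emg(clean_config, seed=2)


def normalized_concat(truth):
    """Amplitude-normalized concatenated envelope matrix plus divisors."""
    x = truth.envelope_concatenated
    div = x.max(axis=1, keepdims=True)
    return x / div, div


@pytest.fixture(scope="session")
def default_matrix(default_dataset):
    _, truth = default_dataset
    x, div = normalized_concat(truth)
    return x, div, truth
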