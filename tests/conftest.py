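import numpy as np
import pytest

from nirscomp import SimulationConfig, generate_trial


@pytest.fixture
def clean_config():
    """Simulator config with every artifact switched off."""
    return SimulationConfig(
        noise_sd=0.0, drift_amplitude=0.0, cardiac_amplitude=0.0, missing_rate=0.0
    )


@pytest.fixture
def clean_trial(clean_config):
    """One artifact-free shoulder-elevation trial plus its ground truth."""
    return generate_trial(clean_config, "SE", seed=11)


@pytest.fixture
def noisy_trial():
    return generate_trial(SimulationConfig(), "SE", seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
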