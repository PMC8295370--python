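import numpy as np
import pytest

from recallnets.synthetic_data import SimulationConfig, simulate_subject


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Five-list subject, 10 electrodes: fast but structurally complete."""
    return SimulationConfig(
        n_lists=5, noise_sd=0.3, network_shared_sd=0.2,
        reinstatement_gain=1.0, stop_prob=0.1, seed=11,
    )


@pytest.fixture(scope="session")
def small_subject(small_config):
    return simulate_subject(small_config)


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free subject: generative signal only, for recovery tests."""
    cfg = SimulationConfig(
        n_lists=5, noise_sd=0.0, network_shared_sd=0.0,
        reinstatement_gain=1.0, stop_prob=0.1, seed=7,
    )
    return simulate_subject(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)
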