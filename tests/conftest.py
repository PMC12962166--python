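import numpy as np
import pytest

from limbcoord.synthetic import CohortConfig, generate_trajectory_trial


@pytest.fixture(scope="session")
def noise_free_config():
    """Degenerate cohort: no phase dispersion, no tracking noise, equal duties."""
    return CohortConfig(
        seed=11,
        kappa_phase=None,
        tracking_noise_sd=0.0,
        landmark_jitter_sd=0.0,
        dropout_frac=0.0,
        duty_factor_fore=0.6,
        duty_factor_hind=0.6,
    )


@pytest.fixture(scope="session")
def noise_free_trial(noise_free_config):
    rec, truth = generate_trajectory_trial(noise_free_config, 0, (44.0, 0.0, 20.0), n_strides=15)
    return rec, truth


@pytest.fixture(scope="session")
def noisy_config():
    return CohortConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
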