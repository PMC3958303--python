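import numpy as np
import pytest

from gaitphase import GaitParams, default_thresholds, simulate_trial


@pytest.fixture(scope="session")
def thresholds():
    """Default thresholds for the default 600 N synthetic subject."""
    return default_thresholds(600.0)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free five-stride walk of the default subject."""
    return simulate_trial(GaitParams(n_strides=5, seed=0))


@pytest.fixture(scope="session")
def noisy_trial():
    """Five-stride walk with moderate wearable-sensor noise."""
    w = 600.0
    return simulate_trial(
        GaitParams(
            n_strides=5,
            sigma_grf=0.02 * w,
            sigma_cop=5.0,
            sigma_ang=2.0,
            sigma_gyro=0.05,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
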