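import numpy as np
import pytest

from fallsense.preprocess import ImuTrial, WindowingConfig
from fallsense.synthdata import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cfg():
    """A small synthetic cohort for structural (non-training) tests."""
    return SynthConfig(n_subjects=5, trials_per_subject=(2, 2),
                       adl_duration_s=(6.0, 10.0), seed=7)


@pytest.fixture(scope="session")
def small_trials(small_cfg):
    trials, manifest = generate_dataset(small_cfg)
    return trials, manifest


@pytest.fixture
def static_fall_trial():
    """A hand-built fall trial: quiet level lying of known geometry.

    500 samples at 1 g along z, fall onset at 400, impact at 500; gyro off.
    """
    samples = np.zeros((500, 6))
    samples[:, 2] = 1.0
    return ImuTrial("S99", "F01", True, samples,
                    onset_frame=400, impact_frame=500, trial_id="S99T01")


@pytest.fixture
def wcfg():
    return WindowingConfig()
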