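import numpy as np
import pytest

import cprkinemat as ck


@pytest.fixture(scope="session")
def correct_pose():
    return ck.reference_posture("correct")


@pytest.fixture(scope="session")
def noiseless_trial(correct_pose):
    """60-s noiseless, drift-free trial at the 'correct' preset."""
    cfg = ck.TrialConfig(
        pose=correct_pose, duration_s=60.0, noise_sd_mm=0.0, seed=7
    )
    return ck.generate_trial(cfg)


@pytest.fixture(scope="session")
def noisy_trial_600s(correct_pose):
    """Default-noise 600-s trial used by the windowing tests."""
    cfg = ck.TrialConfig(pose=correct_pose, duration_s=600.0, seed=42)
    return ck.generate_trial(cfg)


@pytest.fixture(scope="session")
def calibrated_table():
    """One draw from the calibrated feature-level generator."""
    return ck.generate_feature_table(ck.StatsGenConfig(n_rows=10_000, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
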