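import numpy as np
import pytest

from emgintent import synth
from emgintent.types import EMGTrial, MotionClass, SubjectProfile


@pytest.fixture(scope="session")
def synergy():
    return synth.make_default_synergy(0)


@pytest.fixture(scope="session")
def profile():
    return SubjectProfile(
        "S01", gain=np.ones(6), noise_sd=0.01, mains_amplitude=0.05
    )


@pytest.fixture(scope="session")
def burst_trial(synergy, profile):
    """One fast elbow-flexion recording with a single activation cycle."""
    return synth.generate_trial(
        MotionClass("elbow_flexion", "fast"),
        profile,
        synergy,
        n_cycles=1,
        duration_s=3.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def five_burst_trial(synergy, profile):
    return synth.generate_trial(
        MotionClass("arm_abduction_pronated", "fast"),
        profile,
        synergy,
        n_cycles=5,
        duration_s=12.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def mini_dataset():
    """One subject, one single-cycle recording per class (12 recordings)."""
    return synth.generate_dataset(1, 1, seed=3)


@pytest.fixture(scope="session")
def quiet_trial(profile):
    """Baseline-only recording: noise + mains, no activation."""
    rng = np.random.default_rng(99)
    t = np.arange(3000) / 1000.0
    samples = profile.noise_sd * rng.standard_normal((6, 3000))
    samples += profile.mains_amplitude * np.sin(2 * np.pi * 60 * t)[None, :]
    return EMGTrial(
        subject_id="S01",
        label=MotionClass("elbow_flexion", "fast"),
        samples=samples,
        trial_id="quiet",
    )
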