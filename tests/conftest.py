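import numpy as np
import pytest

from neurochoice.synthgen import ClassEffect, SynthConfig, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_synth_cfg():
    """Two subjects, four 1.5-s trials each: the smallest useful dataset."""
    return SynthConfig(n_subjects=2, trials_per_subject=4, buy_fraction=0.5,
                       trial_duration=1.5, seed=7)


@pytest.fixture(scope="session")
def tiny_recordings(tiny_synth_cfg):
    return generate_subject(tiny_synth_cfg, 0)


@pytest.fixture(scope="session")
def strong_effect():
    """The strong injected class effect used for recoverability checks."""
    return ClassEffect(alpha_power_ratio=0.5, fixation_duration_shift=200.0,
                       saccade_amplitude_shift=50.0)


@pytest.fixture(scope="session")
def null_effect():
    return ClassEffect(alpha_power_ratio=1.0, fixation_duration_shift=0.0,
                       saccade_amplitude_shift=0.0)
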