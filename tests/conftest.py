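import numpy as np
import pytest

from fnirsalign import GeneratorConfig, SessionShift, SubjectShift


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Fast generator configuration for unit tests: 4 channels, short
    blocks, short baselines (still 4 segments per class at w=60)."""
    return GeneratorConfig(
        n_channels=4,
        samples_per_task=240,
        baseline_duration=20.0,
        rest_duration=10.0,
        seed=7,
    )


@pytest.fixture
def quiet_config():
    """Noiseless, shift-free configuration: the generator's ideal limit."""
    return GeneratorConfig(
        n_channels=4,
        samples_per_task=600,
        baseline_duration=10.0,
        rest_duration=5.0,
        noise_sd=0.0,
        trend_amplitude=0.0,
        temporal_autocorr=0.0,
        session_shift=SessionShift(
            channel_dropout_probability=0.0,
            mean_drift_scale=0.0,
            gain_jitter=0.0,
        ),
        subject_shift=SubjectShift(
            rotation_angle_scale=0.0,
            baseline_offset_scale=0.0,
            channel_set_size_range=(4, 4),
        ),
        seed=3,
    )


def random_spd(rng, d, scale=1.0):
    a = rng.standard_normal((d, d + 3))
    return scale * (a @ a.T / (d + 3) + 0.1 * np.eye(d))
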