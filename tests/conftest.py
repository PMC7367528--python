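import numpy as np
import pytest

from sonifit import (
    BreathPattern,
    CalibrationProfile,
    ExerciserProfile,
    SessionConfig,
    SmoothingParams,
    gen_breath,
    gen_motion,
)

RATE_HZ = 30.0


@pytest.fixture
def perfect_profile():
    """Guideline-perfect exerciser: 3 s / 3 s, 10 reps, no jitter or noise."""
    return ExerciserProfile()


@pytest.fixture
def perfect_set(perfect_profile):
    """(trace, truth) for a noiseless default set."""
    return gen_motion(perfect_profile, rate_hz=RATE_HZ, seed=7, return_truth=True)


@pytest.fixture
def perfect_breath(perfect_set):
    trace, _ = perfect_set
    return gen_breath(BreathPattern(), trace, rate_hz=RATE_HZ, seed=7)


@pytest.fixture
def default_calibration():
    """Calibration matching the default generator geometry (100..500 mm)."""
    return CalibrationProfile(y_ecc_mm=100.0, y_con_mm=500.0)


@pytest.fixture
def passthrough_config():
    """Session config whose smoothing stage is a no-op (for exactness tests)."""
    return SessionConfig(smoothing=SmoothingParams.identity())


def sine_trace(amplitude=200.0, midpoint=300.0, period=6.0, n_cycles=10,
               rate=RATE_HZ, noise_sd=0.0, seed=0):
    """midpoint + A*sin(2*pi*t/period) sampled over n_cycles periods."""
    from sonifit import MotionTrace

    t = np.arange(int(n_cycles * period * rate) + 1) / rate
    y = midpoint + amplitude * np.sin(2 * np.pi * t / period)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, t.size)
    return MotionTrace.from_arrays(t, y)
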