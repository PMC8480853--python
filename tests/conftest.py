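"""Shared synthetic fixtures.

Everything is generated at test time by the synth module; heavier trial
sets and fits are session-scoped so multiple tests can reuse them.
"""

import numpy as np
import pytest

import envtrack as et


@pytest.fixture(scope="session")
def tracking_trials():
    """Five 60 s, 16-channel trials at 64 Hz with strong tracking (SNR 10)."""
    cfg = et.SynthConfig(n_channels=16, eeg_rate=64.0, duration_s=60.0, snr=10.0, seed=1)
    return et.synth_trialset(cfg, n_trials=5)


@pytest.fixture(scope="session")
def tracking_spec():
    """2-16 Hz model (500 ms window, 32 Hz knots) with short trim margins."""
    return et.ModelSpec(0.5, 32.0, 16, 64.0).with_trim(2.0, 2.0)


@pytest.fixture(scope="session")
def tracking_model(tracking_trials, tracking_spec):
    return et.fit_backward_model(tracking_trials, tracking_spec)


@pytest.fixture(scope="session")
def small_trials():
    """Four light 30 s, 6-channel trials at 32 Hz for cheap fits."""
    cfg = et.SynthConfig(n_channels=6, eeg_rate=32.0, duration_s=30.0, snr=5.0, seed=4)
    return et.synth_trialset(cfg, n_trials=4)


@pytest.fixture(scope="session")
def small_spec():
    return et.ModelSpec(0.5, 16.0, 4, 32.0).with_trim(1.5, 1.5)


def bandlimited_noise(n, rate, lo, hi, rng):
    """White noise band-passed to [lo, hi] Hz, unit variance."""
    from scipy import signal

    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="band", fs=rate, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / y.std()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
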