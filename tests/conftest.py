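"""Shared fixtures: small deterministic containers for unit tests."""

import numpy as np
import pytest

from tribci.containers import ContinuousEEG, EpochSet, LabelBlock


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epochs(rng, n_trials=20, n_channels=4, n_samples=50, fs=100.0,
                start_ms=0.0, y_dec=None, y_class=("a", "b")):
    """Random two-class epoch set with a valid label block."""
    if y_dec is None:
        y_dec = np.r_[np.ones(n_trials // 2, int), 2 * np.ones(n_trials - n_trials // 2, int)]
    data = rng.standard_normal((n_trials, n_channels, n_samples))
    time_ms = start_ms + np.arange(n_samples) / fs * 1000.0
    return EpochSet(data, time_ms, LabelBlock.from_y_dec(y_dec, list(y_class)), fs)


def make_recording(rng, n_samples=2000, n_channels=4, fs=100.0, markers=None,
                   channel_names=None):
    sig = rng.standard_normal((n_samples, n_channels))
    if markers is None:
        markers = np.empty((0, 2), dtype=np.int64)
    return ContinuousEEG(signal=sig, fs=fs, markers=markers,
                         channel_names=channel_names or [])


@pytest.fixture
def epochs(rng):
    return make_epochs(rng)
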