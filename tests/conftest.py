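import numpy as np
import pytest

from erpcase.epochs import EpochSet
from erpcase.simulate import SyntheticParams


def make_epochs(data, fs=250.0, t0=-100.0, condition=None, mirror=None,
                **kw):
    """EpochSet from a raw tensor with an auto-built time axis/labels."""
    data = np.asarray(data, dtype=float)
    n_trials, _, n_samples = data.shape
    time_ms = t0 + np.arange(n_samples) * 1000.0 / fs
    if condition is None:
        condition = np.array(["high", "low"] * ((n_trials + 1) // 2),
                             dtype=object)[:n_trials]
    if mirror is None:
        # period-4 pattern so both mirrors occur within each condition
        mirror = np.array(["left", "left", "right", "right"]
                          * ((n_trials + 3) // 4), dtype=object)[:n_trials]
    return EpochSet(data=data, fs=fs, time_ms=time_ms,
                    condition=np.asarray(condition, dtype=object),
                    mirror=np.asarray(mirror, dtype=object), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_params():
    """Reduced design for fast tests: 8 sensors, 20 trials/condition."""
    return SyntheticParams(
        n_subjects=4, n_sensors=8, n_trials_per_condition=20, seed=7)


@pytest.fixture
def quiet_params():
    """Deterministic signal-only design (no noise, no jitter)."""
    return SyntheticParams(
        n_subjects=2, n_sensors=8, n_trials_per_condition=6,
        noise_sd=0.0, latency_jitter_sd=0.0, trial_amp_sd=0.0,
        between_subject_sigma=0.0, seed=7)


@pytest.fixture
def noisy_epochs(rng):
    """40-trial random epochs, 6 sensors, for generic operation tests."""
    return make_epochs(rng.normal(0, 5, size=(40, 6, 226)))
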