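"""EEG signal-quality gates.

Two checks decide whether a case's data are good enough for single-subject
bootstrap testing:

* the (+/-) reference — averaging with alternating trial polarity, which
  cancels the stimulus-locked signal and leaves a noise-level estimate to
  compare with the regular ERP;
* a bootstrap signal-to-noise ratio: per replicate, ``n_min`` trials
  (the smaller condition count) are drawn with replacement from *each*
  condition — so both picture categories are equally represented — and
  averaged; the ratio of post- to pre-stimulus RMS of the cluster-mean
  waveform is expressed in dB (20*log10 of the amplitude ratio, i.e.
  10*log10 of power).  A case passes if the lower bound of the central
  90% percentile interval reaches the 3 dB threshold.

The resampling equates category representation but tests no condition
effect: it measures signal quality of the overall evoked response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .preprocess import ERPWaveform
from .scoring import SensorCluster


@dataclass(frozen=True)
class SnrConfig:
    n_boot: int = 50_000
    ci_level: float = 0.90
    pre_window_ms: tuple = (-100.0, 0.0)   # [start, 0)
    post_window_ms: tuple | None = None    # (0, epoch_end]; None = full post
    db_threshold: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass(frozen=True)
class SnrResult:
    lower_db: float
    upper_db: float
    passed: bool
    n_min: int


def plus_minus_erp(epochs: EpochSet) -> ERPWaveform:
    """Average with alternating polarity (+1, -1, +1, ... in original
    trial order), divisor = trial count.  With an even number of identical
    trials the result is exactly zero — only noise survives."""
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 trials")
    signs = np.where(np.arange(epochs.n_trials) % 2 == 0, 1.0, -1.0)
    data = (signs[:, None, None] * epochs.data).sum(axis=0) / epochs.n_trials
    return ERPWaveform(
        data=data,
        fs=epochs.fs,
        time_ms=epochs.time_ms,
        n_trials_averaged=epochs.n_trials,
        condition="plus_minus",
    )


def _rms(x: np.ndarray, axis=-1) -> np.ndarray:
    return np.sqrt(np.mean(np.square(x), axis=axis))


def snr_db(waveform_1d: np.ndarray, pre_mask: np.ndarray,
           post_mask: np.ndarray) -> float:
    """dB SNR of a single cluster-mean waveform."""
    pre = _rms(waveform_1d[pre_mask])
    if pre == 0:
        raise ValueError("pre-stimulus RMS is zero (degenerate noiseless input)")
    return float(20.0 * np.log10(_rms(waveform_1d[post_mask]) / pre))


def snr_ci(epochs: EpochSet, cluster: SensorCluster,
           config: SnrConfig = SnrConfig()) -> SnrResult:
    """Bootstrap CI of the post/pre RMS ratio on the cluster-mean ERP."""
    cluster.validate(epochs.n_sensors)
    counts = epochs.condition_counts()
    n_min = min(counts.values())
    pre_mask = epochs.time_mask(*config.pre_window_ms,
                                include_start=True, include_end=False)
    post_end = epochs.time_ms[-1] if config.post_window_ms is None \
        else config.post_window_ms[1]
    post_start = 0.0 if config.post_window_ms is None else config.post_window_ms[0]
    post_mask = epochs.time_mask(post_start, post_end,
                                 include_start=False, include_end=True)
    if not pre_mask.any() or not post_mask.any():
        raise ValueError("pre/post windows contain no samples")
    if (pre_mask & post_mask).any():
        raise ValueError("pre and post windows overlap")

    trial_series = epochs.data[:, cluster.indices, :].mean(axis=1)  # trials x samples
    # degenerate check on the full average before resampling
    snr_db(trial_series.mean(axis=0), pre_mask, post_mask)

    rng = np.random.default_rng(config.seed)
    groups = [trial_series[epochs.condition == c] for c in sorted(counts)]
    dbs = np.empty(config.n_boot)
    chunk = max(1, int(4_000_000
                       // max(n_min * trial_series.shape[1], 1)))
    for lo in range(0, config.n_boot, chunk):
        hi = min(lo + chunk, config.n_boot)
        m = hi - lo
        # n_min draws from each condition, averaged together
        rep = np.zeros((m, trial_series.shape[1]))
        for g in groups:
            idx = rng.integers(0, g.shape[0], size=(m, n_min))
            rep += g[idx].mean(axis=1)
        rep /= len(groups)
        pre = _rms(rep[:, pre_mask])
        post = _rms(rep[:, post_mask])
        if np.any(pre == 0):
            raise ValueError("pre-stimulus RMS is zero in a replicate")
        dbs[lo:hi] = 20.0 * np.log10(post / pre)

    tail = 100.0 * (1.0 - config.ci_level) / 2.0
    lower, upper = np.percentile(dbs, [tail, 100.0 - tail])
    return SnrResult(
        lower_db=float(lower),
        upper_db=float(upper),
        passed=bool(lower >= config.db_threshold),
        n_min=n_min,
    )
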