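"""Preprocessing chain for epoched EEG.

Implements the standard chain used before component scoring: Butterworth
band limiting (40 Hz low-pass of order 19, 0.06 Hz high-pass of order 4,
half-power cutoffs), baseline adjustment over the 100 ms pre-stimulus
interval, average re-referencing, simple absolute-threshold artifact
rejection, seeded trial-count equating between conditions, and condition
averaging.

Order of operations: baseline first, then average reference.  With that
order both identities hold simultaneously afterwards: every trial's
baseline mean is zero per sensor, and the across-sensor sum is zero at
every sample.

Filters default to zero-phase (forward-backward) application so that
window means carry no phase delay; causal application is available for
fidelity experiments.  High-order designs are realized as second-order
sections for numerical stability — the contract is the magnitude response,
not a coefficient layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .epochs import EpochSet


@dataclass(frozen=True)
class FilterSpec:
    lowpass_cutoff: float = 40.0
    lowpass_order: int = 19
    highpass_cutoff: float = 0.06
    highpass_order: int = 4
    family: str = "butterworth"
    phase_mode: str = "zero_phase"  # or "causal"

    def __post_init__(self) -> None:
        if not (0 < self.highpass_cutoff < self.lowpass_cutoff):
            raise ValueError("require 0 < highpass_cutoff < lowpass_cutoff")
        if self.lowpass_order < 1 or self.highpass_order < 1:
            raise ValueError("filter orders must be >= 1")
        if self.phase_mode not in ("zero_phase", "causal"):
            raise ValueError("phase_mode must be 'zero_phase' or 'causal'")

    def design_sos(self, fs: float) -> np.ndarray:
        """Cascaded SOS of high-pass then low-pass (half-power cutoffs)."""
        if self.lowpass_cutoff >= fs / 2:
            raise ValueError(
                f"lowpass cutoff {self.lowpass_cutoff} Hz >= Nyquist {fs / 2} Hz"
            )
        lp = signal.butter(self.lowpass_order, self.lowpass_cutoff,
                           btype="low", fs=fs, output="sos")
        hp = signal.butter(self.highpass_order, self.highpass_cutoff,
                           btype="high", fs=fs, output="sos")
        return np.vstack([hp, lp])

    def gain_at(self, freq_hz: float, fs: float) -> float:
        """Single-pass amplitude gain of the cascade at ``freq_hz``."""
        sos = self.design_sos(fs)
        _, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
        return float(np.abs(h[0]))


@dataclass
class ERPWaveform:
    """Sensors x samples mean waveform (microvolts)."""

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    n_trials_averaged: int
    condition: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[1] != self.time_ms.size:
            raise ValueError("waveform must be sensors x samples matching time axis")
        if self.n_trials_averaged < 1:
            raise ValueError("n_trials_averaged must be >= 1")


def apply_filters(epochs: EpochSet, spec: FilterSpec = FilterSpec()) -> EpochSet:
    """Filter every trial/sensor series with the cascaded band filters."""
    sos = spec.design_sos(epochs.fs)
    if spec.phase_mode == "zero_phase":
        n_sections = sos.shape[0]
        padlen = 3 * (2 * n_sections + 1)
        if epochs.n_samples <= padlen:
            raise ValueError(
                f"epoch too short for zero-phase filtering: need more than "
                f"{padlen} samples, got {epochs.n_samples}"
            )
        filtered = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    else:
        filtered = signal.sosfilt(sos, epochs.data, axis=-1)
    return replace(
        epochs,
        data=np.ascontiguousarray(filtered),
        provenance=epochs.provenance + f"; filtered ({spec.phase_mode})",
    )


def baseline_and_reference(epochs: EpochSet,
                           baseline_ms: tuple = (-100.0, 0.0)) -> EpochSet:
    """Baseline-adjust then re-reference to the average reference.

    The baseline interval is half-open ``[start, 0)`` — the onset sample
    belongs to the post-stimulus period.
    """
    if baseline_ms[0] >= baseline_ms[1] or baseline_ms[1] > 0:
        raise ValueError("baseline interval must precede stimulus onset")
    mask = epochs.time_mask(baseline_ms[0], baseline_ms[1],
                            include_start=True, include_end=False)
    if not mask.any():
        raise ValueError(
            f"baseline interval {baseline_ms} contains no samples at fs={epochs.fs}"
        )
    data = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    data = data - data.mean(axis=1, keepdims=True)  # average reference
    return replace(epochs, data=data,
                   provenance=epochs.provenance + "; baseline+avg-ref")


def reject_artifacts(epochs: EpochSet, abs_threshold: float = 100.0):
    """Drop trials whose absolute amplitude exceeds the threshold anywhere.

    Returns ``(kept_epochs, log)``; the log has one record per dropped
    trial with the location and value of its worst excursion.
    """
    if abs_threshold <= 0:
        raise ValueError("threshold must be positive")
    absmax = np.abs(epochs.data).reshape(epochs.n_trials, -1)
    worst_flat = absmax.argmax(axis=1)
    worst_val = absmax[np.arange(epochs.n_trials), worst_flat]
    bad = worst_val > abs_threshold
    if bad.all():
        raise ValueError("all trials exceed the artifact threshold")
    log = []
    for i in np.flatnonzero(bad):
        sensor, sample = np.unravel_index(worst_flat[i],
                                          (epochs.n_sensors, epochs.n_samples))
        log.append(
            {
                "trial_index": int(i),
                "sensor": int(sensor),
                "sample": int(sample),
                "value": float(epochs.data[i, sensor, sample]),
            }
        )
    kept = epochs.subset(np.flatnonzero(~bad),
                         note=f"artifact rejection (+/-{abs_threshold} uV)")
    return kept, log


def write_rejection_log(log: list, path) -> None:
    """JSON-lines rejection log."""
    with open(path, "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec) + "\n")


def equate_trials(epochs: EpochSet, seed) -> EpochSet:
    """Equate condition trial counts by seeded random subsampling of the
    larger condition (random permutation, keep the first ``n_min``); the
    smaller condition is untouched and trial order is preserved."""
    rng = np.random.default_rng(seed)
    counts = epochs.condition_counts()
    if set(counts) != {"high", "low"}:
        raise ValueError("both conditions must be present")
    n_min = min(counts.values())
    keep = np.zeros(epochs.n_trials, dtype=bool)
    for cond in ("high", "low"):
        idx = np.flatnonzero(epochs.condition == cond)
        if idx.size > n_min:
            idx = idx[np.sort(rng.permutation(idx.size)[:n_min])]
        keep[idx] = True
    if keep.all():
        return epochs
    return epochs.subset(np.flatnonzero(keep), note=f"equated to {n_min}/{n_min}")


def compute_erp(epochs: EpochSet, condition: str) -> ERPWaveform:
    """Arithmetic mean waveform over the trials of one condition."""
    mask = epochs.condition_mask(condition)
    return ERPWaveform(
        data=epochs.data[mask].mean(axis=0),
        fs=epochs.fs,
        time_ms=epochs.time_ms,
        n_trials_averaged=int(mask.sum()),
        condition=condition,
    )


def erp_difference(erp_high: ERPWaveform, erp_low: ERPWaveform) -> ERPWaveform:
    if erp_high.data.shape != erp_low.data.shape:
        raise ValueError("waveform shapes differ")
    return ERPWaveform(
        data=erp_high.data - erp_low.data,
        fs=erp_high.fs,
        time_ms=erp_high.time_ms,
        n_trials_averaged=min(erp_high.n_trials_averaged, erp_low.n_trials_averaged),
        condition="difference",
    )


def preprocess(epochs: EpochSet, filter_spec: FilterSpec | None = FilterSpec(),
               baseline_ms: tuple = (-100.0, 0.0),
               artifact_threshold: float | None = 100.0,
               equate_seed=0) -> EpochSet:
    """The full chain: filter -> baseline+reference -> reject -> equate."""
    out = epochs
    if filter_spec is not None:
        out = apply_filters(out, filter_spec)
    out = baseline_and_reference(out, baseline_ms)
    if artifact_threshold is not None:
        out, _ = reject_artifacts(out, artifact_threshold)
    out = equate_trials(out, equate_seed)
    return out
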