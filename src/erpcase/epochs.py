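"""Epoched-EEG container and on-disk formats.

An :class:`EpochSet` holds one subject x behavior-system block of epoched
EEG: a trials x sensors x samples amplitude tensor (microvolts) together
with the per-trial condition (high/low arousal) and mirror (left/right
picture version) labels.  It is the unit every analysis stage operates on.

On disk an EpochSet is an ``.npz`` tensor plus a CSV trial-metadata sidecar
(columns exactly ``trial_index, condition, mirror``); FIF export/import via
:mod:`mne` is provided for interoperability with standard EEG tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CONDITIONS = ("high", "low")
MIRRORS = ("left", "right")


@dataclass
class EpochSet:
    """Trials x sensors x samples amplitude tensor with trial labels.

    Parameters
    ----------
    data
        Array of shape ``(n_trials, n_sensors, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    time_ms
        Per-sample times in milliseconds; strictly increasing with step
        ``1000 / fs`` and containing 0 (stimulus onset).
    condition, mirror
        Per-trial labels (``high``/``low`` and ``left``/``right``).
    """

    data: np.ndarray
    fs: float
    time_ms: np.ndarray
    condition: np.ndarray
    mirror: np.ndarray
    subject_id: str = "S00"
    system: str = "unspecified"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.time_ms = np.asarray(self.time_ms, dtype=np.float64)
        self.condition = np.asarray(self.condition, dtype=object)
        self.mirror = np.asarray(self.mirror, dtype=object)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_sensors, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n_trials, _, n_samples = self.data.shape
        if len(self.condition) != n_trials or len(self.mirror) != n_trials:
            raise ValueError("label vectors must have one entry per trial")
        if len(self.time_ms) != n_samples:
            raise ValueError("time axis length must equal sample count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("amplitudes must be finite")
        step = 1000.0 / self.fs
        if n_samples > 1:
            diffs = np.diff(self.time_ms)
            if not np.allclose(diffs, step, rtol=0, atol=1e-6 * step):
                raise ValueError("time axis must be uniform with step 1000/fs")
        if np.min(np.abs(self.time_ms)) > 1e-6 * step:
            raise ValueError("time axis must include 0 (stimulus onset)")

    # -- basic properties -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def condition_counts(self) -> dict:
        return {c: int(np.sum(self.condition == c)) for c in np.unique(self.condition)}

    def condition_mask(self, condition: str) -> np.ndarray:
        mask = self.condition == condition
        if not mask.any():
            raise ValueError(f"condition {condition!r} not present")
        return mask

    # -- derived sets -----------------------------------------------------
    def subset(self, trial_indices: np.ndarray, note: str = "") -> "EpochSet":
        """New EpochSet holding the given trials (original order preserved
        if the indices are sorted)."""
        idx = np.asarray(trial_indices)
        prov = self.provenance + (f"; {note}" if note else "")
        return replace(
            self,
            data=self.data[idx],
            condition=self.condition[idx],
            mirror=self.mirror[idx],
            provenance=prov,
        )

    def with_conditions(self, condition: np.ndarray, note: str = "") -> "EpochSet":
        """Same data with relabelled conditions (pseudo-condition tests)."""
        prov = self.provenance + (f"; {note}" if note else "")
        return replace(self, condition=np.asarray(condition, dtype=object), provenance=prov)

    def time_mask(self, start_ms: float, end_ms: float,
                  include_start: bool = True, include_end: bool = True) -> np.ndarray:
        """Boolean sample mask for a time interval; endpoint inclusion is
        explicit because windows in this pipeline mix conventions
        (scoring windows are closed, the baseline is half-open)."""
        t = self.time_ms
        lo = t >= start_ms if include_start else t > start_ms
        hi = t <= end_ms if include_end else t < end_ms
        return lo & hi


# -- on-disk formats ------------------------------------------------------

def save_npz(epochs: EpochSet, path: str | Path) -> None:
    """Write tensor to ``<path>.npz`` (or path as given) and trial metadata
    to the CSV sidecar ``<stem>_trials.csv``."""
    path = Path(path)
    np.savez_compressed(
        path,
        data=epochs.data.astype(np.float32),
        fs=epochs.fs,
        time_ms=epochs.time_ms,
        subject_id=np.str_(epochs.subject_id),
        system=np.str_(epochs.system),
        provenance=np.str_(epochs.provenance),
    )
    meta = pd.DataFrame(
        {
            "trial_index": np.arange(epochs.n_trials),
            "condition": epochs.condition,
            "mirror": epochs.mirror,
        }
    )
    stem = path.with_suffix("") if path.suffix == ".npz" else path
    meta.to_csv(Path(str(stem) + "_trials.csv"), index=False)


def load_npz(path: str | Path) -> EpochSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    with np.load(path, allow_pickle=False) as z:
        data = z["data"].astype(np.float64)
        fs = float(z["fs"])
        time_ms = z["time_ms"]
        subject_id = str(z["subject_id"])
        system = str(z["system"])
        provenance = str(z["provenance"])
    meta = pd.read_csv(Path(str(path.with_suffix("")) + "_trials.csv"))
    return EpochSet(
        data=data,
        fs=fs,
        time_ms=time_ms,
        condition=meta["condition"].to_numpy(dtype=object),
        mirror=meta["mirror"].to_numpy(dtype=object),
        subject_id=subject_id,
        system=system,
        provenance=provenance,
    )


def to_mne(epochs: EpochSet):
    """Convert to an :class:`mne.EpochsArray` (volts internally, per MNE
    convention) with condition/mirror in the metadata frame."""
    import mne

    info = mne.create_info(
        ch_names=[f"E{i + 1}" for i in range(epochs.n_sensors)],
        sfreq=epochs.fs,
        ch_types="eeg",
    )
    tmin = epochs.time_ms[0] / 1000.0
    ep = mne.EpochsArray(epochs.data * 1e-6, info, tmin=tmin, verbose="error")
    ep.metadata = pd.DataFrame(
        {"condition": epochs.condition, "mirror": epochs.mirror}
    )
    return ep


def save_fif(epochs: EpochSet, path: str | Path) -> None:
    to_mne(epochs).save(str(path), overwrite=True, verbose="error")


def load_fif(path: str | Path, subject_id: str = "S00",
             system: str = "unspecified") -> EpochSet:
    import mne

    ep = mne.read_epochs(str(path), preload=True, verbose="error")
    if ep.metadata is None or not {"condition", "mirror"} <= set(ep.metadata.columns):
        raise ValueError("FIF epochs must carry condition/mirror metadata")
    return EpochSet(
        data=ep.get_data(copy=True) * 1e6,
        fs=float(ep.info["sfreq"]),
        time_ms=ep.times * 1000.0,
        condition=ep.metadata["condition"].to_numpy(dtype=object),
        mirror=ep.metadata["mirror"].to_numpy(dtype=object),
        subject_id=subject_id,
        system=system,
        provenance=f"loaded from {path}",
    )
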