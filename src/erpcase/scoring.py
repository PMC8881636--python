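"""EPN/LPP component scoring.

Components are scored as cluster-mean amplitudes: the average over a fixed
sensor cluster and a time window, either the a-priori group window (fixed
mode) or an individually adapted window (adaptive mode).  The adaptive
search slides a window of the component's span (EPN 60 ms, LPP 100 ms) in
1-sample steps across the component's search range (EPN 150-350 ms, LPP
350-750 ms) and keeps the window maximizing the signed high-minus-low
difference: most negative for the EPN, most positive for the LPP.  Ties go
to the earliest start.

Window endpoints are inclusive; at 250 Hz a 60-ms window therefore spans
``round(60 * 250 / 1000) + 1 = 16`` samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .epochs import EpochSet
from .preprocess import ERPWaveform, compute_erp, erp_difference


@dataclass(frozen=True)
class SensorCluster:
    """A named set of sensor indices (0-based into the data tensor)."""

    name: str
    sensor_ids: tuple

    def __post_init__(self) -> None:
        ids = tuple(sorted(set(int(i) for i in self.sensor_ids)))
        if not ids:
            raise ValueError("cluster must contain at least one sensor")
        if any(i < 0 for i in ids):
            raise ValueError("sensor ids must be non-negative")
        object.__setattr__(self, "sensor_ids", ids)

    def validate(self, n_sensors: int) -> None:
        if self.sensor_ids[-1] >= n_sensors:
            raise ValueError(
                f"cluster {self.name!r} references sensor {self.sensor_ids[-1]} "
                f"but data has only {n_sensors} sensors"
            )

    @property
    def indices(self) -> np.ndarray:
        return np.asarray(self.sensor_ids, dtype=int)


@dataclass(frozen=True)
class ComponentSpec:
    """Definition of an ERP component for scoring.

    ``direction`` is the expected sign of the high-minus-low difference:
    -1 for the EPN (relative negativity), +1 for the LPP.
    """

    name: str
    cluster: SensorCluster
    fixed_window: tuple  # (start_ms, end_ms), inclusive
    search_range: tuple  # (start_ms, end_ms), inclusive
    span_ms: float
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")
        if self.span_ms <= 0:
            raise ValueError("span must be positive")
        if self.search_range[1] - self.search_range[0] < self.span_ms:
            raise ValueError(
                f"component {self.name!r}: span {self.span_ms} ms exceeds "
                f"search range {self.search_range}"
            )


@dataclass(frozen=True)
class ComponentScore:
    component: str
    window_used: tuple
    mode: str  # "fixed" | "adaptive"
    mean_high: float
    mean_low: float
    difference: float  # mean_high - mean_low, exactly


def load_default_clusters(n_sensors: int = 256) -> dict:
    """The occipito-parietal (EPN) and centro-parietal (LPP) clusters for
    256-lead geodesic-net data.

    The shipped lists use the net's 1-based sensor labels; they are
    converted to 0-based indices here.  Label 257 (the vertex reference of
    the 257-channel montage) is dropped when the data array has fewer than
    257 channels.
    """
    text = resources.files("erpcase.data").joinpath("clusters_egi256.json").read_text()
    raw = json.loads(text)
    out = {}
    for key in ("posterior", "central"):
        labels = raw[key]["labels"]
        ids = [lab - 1 for lab in labels if lab - 1 < n_sensors]
        if not ids:
            raise ValueError(f"no sensors of cluster {key!r} fit n_sensors={n_sensors}")
        out[key] = SensorCluster(name=raw[key]["name"], sensor_ids=tuple(ids))
    return out


def scaled_clusters(n_sensors: int) -> dict:
    """Cluster stand-ins for reduced sensor counts (simulation studies):
    the last quarter of sensors plays the posterior cluster, the quarter
    before it the central cluster."""
    if n_sensors >= 256:
        return load_default_clusters(n_sensors)
    q = max(1, n_sensors // 4)
    posterior = tuple(range(n_sensors - q, n_sensors))
    central = tuple(range(n_sensors - 2 * q, n_sensors - q))
    return {
        "posterior": SensorCluster("posterior (scaled)", posterior),
        "central": SensorCluster("central (scaled)", central),
    }


def default_component_specs(n_sensors: int = 256) -> dict:
    """EPN and LPP specs with the study's windows and clusters."""
    clusters = scaled_clusters(n_sensors)
    return {
        "EPN": ComponentSpec(
            name="EPN",
            cluster=clusters["posterior"],
            fixed_window=(240.0, 300.0),
            search_range=(150.0, 350.0),
            span_ms=60.0,
            direction=-1,
        ),
        "LPP": ComponentSpec(
            name="LPP",
            cluster=clusters["central"],
            fixed_window=(380.0, 480.0),
            search_range=(350.0, 750.0),
            span_ms=100.0,
            direction=+1,
        ),
    }


# -- scoring primitives ---------------------------------------------------

def window_length_samples(span_ms: float, fs: float) -> int:
    """Samples in a window of ``span_ms`` with inclusive endpoints."""
    return int(round(span_ms * fs / 1000.0)) + 1


def mean_cluster_amplitude(waveform: ERPWaveform, cluster: SensorCluster,
                           window: tuple) -> float:
    """Mean amplitude over cluster sensors and all samples with
    ``window[0] <= t <= window[1]`` (inclusive endpoints)."""
    cluster.validate(waveform.data.shape[0])
    t = waveform.time_ms
    mask = (t >= window[0]) & (t <= window[1])
    if not mask.any():
        raise ValueError(f"window {window} contains no samples at fs={waveform.fs}")
    return float(waveform.data[np.ix_(cluster.indices, np.flatnonzero(mask))].mean())


def cluster_mean_series(waveform: ERPWaveform, cluster: SensorCluster) -> np.ndarray:
    cluster.validate(waveform.data.shape[0])
    return waveform.data[cluster.indices].mean(axis=0)


def sliding_window_means(series: np.ndarray, wlen: int) -> np.ndarray:
    """Means of every contiguous window of ``wlen`` samples (valid mode)."""
    if wlen > series.size:
        raise ValueError("window longer than series")
    c = np.concatenate(([0.0], np.cumsum(series)))
    return (c[wlen:] - c[:-wlen]) / wlen


def adaptive_window(diff: ERPWaveform, spec: ComponentSpec) -> tuple:
    """Individually adapted component window.

    Returns the (start_ms, end_ms) of the span-length window inside the
    search range that maximizes ``direction x window-mean`` of the
    cluster-mean difference series, earliest start on ties.
    """
    t = diff.time_ms
    in_range = (t >= spec.search_range[0]) & (t <= spec.search_range[1])
    idx = np.flatnonzero(in_range)
    if idx.size == 0:
        raise ValueError(f"search range {spec.search_range} outside epoch")
    series = cluster_mean_series(diff, spec.cluster)[idx]
    wlen = window_length_samples(spec.span_ms, diff.fs)
    if wlen > series.size:
        raise ValueError(
            f"component {spec.name!r}: span {spec.span_ms} ms longer than "
            f"search range at fs={diff.fs}"
        )
    means = sliding_window_means(series, wlen)
    best = int(np.argmax(spec.direction * means))  # argmax -> earliest tie
    start = idx[best]
    return (float(t[start]), float(t[start + wlen - 1]))


def score_component(epochs: EpochSet, spec: ComponentSpec, mode: str = "adaptive",
                    ) -> ComponentScore:
    """Score one component on preprocessed epochs.

    Computes the high/low condition ERPs, picks the window per ``mode``
    and returns the cluster-mean amplitudes and their difference.  The
    selected window is recorded for reuse by the bootstrap.
    """
    if mode not in ("fixed", "adaptive"):
        raise ValueError("mode must be 'fixed' or 'adaptive'")
    erp_high = compute_erp(epochs, "high")
    erp_low = compute_erp(epochs, "low")
    if mode == "fixed":
        window = (float(spec.fixed_window[0]), float(spec.fixed_window[1]))
    else:
        window = adaptive_window(erp_difference(erp_high, erp_low), spec)
    mean_high = mean_cluster_amplitude(erp_high, spec.cluster, window)
    mean_low = mean_cluster_amplitude(erp_low, spec.cluster, window)
    return ComponentScore(
        component=spec.name,
        window_used=window,
        mode=mode,
        mean_high=mean_high,
        mean_low=mean_low,
        difference=mean_high - mean_low,
    )
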