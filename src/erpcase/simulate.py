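"""Synthetic epoched-EEG generator.

Emulates the study design every downstream stage assumes: per subject and
behavior system (sexual reproduction, disease avoidance, predator fear) a
block of high- and low-arousal picture trials, 256 sensors sampled at
250 Hz, epochs spanning -100..800 ms, with left/right mirror labels
balanced within condition.

Per-trial additive model::

    trial = noise + base evoked shape + condition-dependent effect bumps

* Noise is spatially correlated 1/f^beta noise: a shared (all-sensor)
  power-law series and sensor-independent series, mixed so each sensor's
  marginal SD is ``noise_sd`` and the inter-sensor correlation is
  ``spatial_corr``.
* The base evoked shape is condition-independent: a positive Hann bump on
  the posterior cluster and a negative one on the central cluster (real
  posterior ERPs are positive-going, central ones negative-going); it gives
  the epochs genuine post-stimulus signal for SNR checks.
* The EPN effect adds a negative Hann bump (span 60 ms) on the posterior
  cluster to high-arousal trials; the LPP effect a positive bump (span
  100 ms) on the central cluster.  Per-trial amplitude and latency vary by
  ``trial_amp_sd`` and ``latency_jitter_sd``; per-subject amplitudes carry
  a lognormal scale factor to emulate individual variation.
* Mirror labels carry no signal by default; ``mirror_effect_amp`` can
  inject an EPN-shaped left-trial bump to exercise specificity power.

Everything is reproducible from ``(seed, subject_index, system)`` through
a fixed counter-based child-seed scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

from .epochs import EpochSet
from .scoring import SensorCluster, scaled_clusters

DEFAULT_SYSTEMS = ("sexual_reproduction", "disease_avoidance", "predator_fear")

# Effect peak amplitudes (uV).  A Hann bump's mean weight over its support
# is ~0.5, so peaks of twice the group-mean differences reported for the
# three systems yield realized window-mean differences of about
# EPN -2.8/-2.1/-1.3 uV and LPP +2.2/+1.3/+0.6 uV.
DEFAULT_EPN_AMPS = {
    "sexual_reproduction": -5.6,
    "disease_avoidance": -4.1,
    "predator_fear": -2.6,
}
DEFAULT_LPP_AMPS = {
    "sexual_reproduction": 4.3,
    "disease_avoidance": 2.7,
    "predator_fear": 1.3,
}

_NOISE_CHUNK = 128  # trials per noise block; fixed so draws are reproducible


@dataclass
class SyntheticParams:
    """Generator controls; defaults are the study's design sizes."""

    n_subjects: int = 16
    n_sensors: int = 256
    fs: float = 250.0
    epoch_start_ms: float = -100.0
    epoch_end_ms: float = 800.0
    n_trials_per_condition: int = 600
    systems: tuple = DEFAULT_SYSTEMS
    noise_sd: float = 20.0
    noise_exponent: float = 1.0
    spatial_corr: float = 0.3
    base_erp_amp: float = 4.0
    epn_effect_amp: Mapping | float = field(default_factory=lambda: dict(DEFAULT_EPN_AMPS))
    lpp_effect_amp: Mapping | float = field(default_factory=lambda: dict(DEFAULT_LPP_AMPS))
    effect_latency_ms: Mapping = field(default_factory=lambda: {"EPN": 270.0, "LPP": 450.0})
    effect_span_ms: Mapping = field(default_factory=lambda: {"EPN": 60.0, "LPP": 100.0})
    latency_jitter_sd: float = 20.0
    trial_amp_sd: float = 1.0
    between_subject_sigma: float = 0.47
    mirror_effect_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.epoch_start_ms < 0 < self.epoch_end_ms):
            raise ValueError("epoch must span stimulus onset: start < 0 < end")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        for name in ("n_subjects", "n_sensors", "n_trials_per_condition"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_sd < 0 or self.latency_jitter_sd < 0 or self.trial_amp_sd < 0:
            raise ValueError("noise/jitter/amplitude SDs must be non-negative")
        if not (0.0 <= self.spatial_corr <= 1.0):
            raise ValueError("spatial_corr must lie in [0, 1]")
        for comp in ("EPN", "LPP"):
            lat = self.effect_latency_ms[comp]
            half = self.effect_span_ms[comp] / 2.0
            if lat - half < self.epoch_start_ms or lat + half > self.epoch_end_ms:
                raise ValueError(
                    f"effect support of component {comp} "
                    f"({lat - half:.0f}..{lat + half:.0f} ms) lies outside the epoch"
                )

    def time_axis(self) -> np.ndarray:
        step = 1000.0 / self.fs
        n = int(round((self.epoch_end_ms - self.epoch_start_ms) / step)) + 1
        return self.epoch_start_ms + np.arange(n) * step

    def amp_for(self, component: str, system: str) -> float:
        amps = self.epn_effect_amp if component == "EPN" else self.lpp_effect_amp
        if isinstance(amps, Mapping):
            return float(amps[system])
        return float(amps)

    def clusters(self) -> dict:
        return scaled_clusters(self.n_sensors)


def params_to_yaml(params: SyntheticParams, path) -> None:
    d = asdict(params)
    d["systems"] = list(d["systems"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def params_from_yaml(path) -> SyntheticParams:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["systems"] = tuple(d["systems"])
    return SyntheticParams(**d)


# -- primitives -----------------------------------------------------------

def hann_bump(time_ms: np.ndarray, center_ms, span_ms: float) -> np.ndarray:
    """Hann window: peak 1 at the center, zero outside +/- span/2.

    ``center_ms`` may be an array (per-trial jittered centers), in which
    case the result broadcasts to ``centers x samples``.
    """
    c = np.atleast_1d(np.asarray(center_ms, dtype=float))[:, None]
    x = (time_ms[None, :] - c) / span_ms
    w = np.where(np.abs(x) <= 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * x)), 0.0)
    return w[0] if np.isscalar(center_ms) or np.ndim(center_ms) == 0 else w


def powerlaw_noise(rng: np.random.Generator, n_series: int, n_samples: int,
                   exponent: float, fs: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise series (rows independent).

    Built in the frequency domain: complex-Gaussian coefficients with
    amplitude f^(-exponent/2); DC (and Nyquist) zeroed; normalized so each
    time sample has variance 1 exactly in expectation.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    w = np.zeros_like(freqs)
    w[1:] = freqs[1:] ** (-exponent / 2.0)
    if n_samples % 2 == 0:
        w[-1] = 0.0  # Nyquist bin must be real; drop it instead
    z = rng.standard_normal((n_series, freqs.size)) \
        + 1j * rng.standard_normal((n_series, freqs.size))
    x = np.fft.irfft(z * w[None, :], n=n_samples, axis=-1)
    # Var(x_t) = 4 * sum(w^2) / N^2 for this construction
    x *= n_samples / (2.0 * np.sqrt(np.sum(w ** 2)))
    return x


def _seed_seq(seed: int, *keys: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]])


def subject_scales(params: SyntheticParams, subject_index: int) -> dict:
    """Per-subject lognormal (median 1) effect scale factors, one per
    component, shared across systems — a subject with big EPN effects has
    them in every block."""
    rng = np.random.default_rng(_seed_seq(params.seed, subject_index, 0xA5))
    z = rng.standard_normal(2)
    return {
        "EPN": float(np.exp(params.between_subject_sigma * z[0])),
        "LPP": float(np.exp(params.between_subject_sigma * z[1])),
    }


def generate_subject(params: SyntheticParams, subject_index: int,
                     system: str) -> EpochSet:
    """One subject x system block of synthetic epochs.

    Fully reproducible from ``(params.seed, subject_index, system)``.
    """
    if subject_index >= params.n_subjects:
        raise ValueError("subject_index out of range")
    if system not in params.systems:
        raise ValueError(f"unknown system {system!r}")
    sys_idx = params.systems.index(system)
    rng = np.random.default_rng(_seed_seq(params.seed, subject_index, sys_idx, 1))

    time_ms = params.time_axis()
    n_samples = time_ms.size
    ntc = params.n_trials_per_condition
    n = 2 * ntc

    condition = np.array(["high"] * ntc + ["low"] * ntc, dtype=object)
    mirror = np.empty(n, dtype=object)
    for start in (0, ntc):  # balanced within condition
        half = ntc // 2
        mirror[start:start + half] = "left"
        mirror[start + half:start + ntc] = "right"
        if ntc % 2:
            mirror[start + ntc - 1] = "left"

    data = np.zeros((n, params.n_sensors, n_samples))

    # -- noise (chunked to bound memory at full design size) -------------
    if params.noise_sd > 0:
        rho = params.spatial_corr
        for lo in range(0, n, _NOISE_CHUNK):
            hi = min(lo + _NOISE_CHUNK, n)
            m = hi - lo
            shared = powerlaw_noise(rng, m, n_samples,
                                    params.noise_exponent, params.fs)
            indep = powerlaw_noise(rng, m * params.n_sensors, n_samples,
                                   params.noise_exponent, params.fs)
            indep = indep.reshape(m, params.n_sensors, n_samples)
            data[lo:hi] = params.noise_sd * (
                np.sqrt(rho) * shared[:, None, :] + np.sqrt(1.0 - rho) * indep
            )

    clusters = params.clusters()
    posterior, central = clusters["posterior"], clusters["central"]

    # -- condition-independent evoked shape -------------------------------
    if params.base_erp_amp != 0:
        base_post = params.base_erp_amp * hann_bump(time_ms, 250.0, 200.0)
        base_cent = -params.base_erp_amp * hann_bump(time_ms, 450.0, 300.0)
        data[:, posterior.indices, :] += base_post[None, None, :]
        data[:, central.indices, :] += base_cent[None, None, :]

    # -- condition-dependent effects (high-arousal trials only) ----------
    scales = subject_scales(params, subject_index)
    high_idx = np.flatnonzero(condition == "high")
    for comp, cluster in (("EPN", posterior), ("LPP", central)):
        amp = params.amp_for(comp, system) * scales[comp]
        trial_amp = amp + rng.normal(0.0, params.trial_amp_sd, size=high_idx.size)
        centers = params.effect_latency_ms[comp] + rng.normal(
            0.0, params.latency_jitter_sd, size=high_idx.size)
        half = params.effect_span_ms[comp] / 2.0
        centers = np.clip(centers, params.epoch_start_ms + half,
                          params.epoch_end_ms - half)
        bumps = trial_amp[:, None] * hann_bump(time_ms, centers,
                                               params.effect_span_ms[comp])
        data[np.ix_(high_idx, cluster.indices)] += bumps[:, None, :]

    # -- optional mirror-specific signal (EPN-shaped, left trials) --------
    if params.mirror_effect_amp != 0:
        left_idx = np.flatnonzero(mirror == "left")
        bump = params.mirror_effect_amp * hann_bump(
            time_ms, params.effect_latency_ms["EPN"], params.effect_span_ms["EPN"])
        data[np.ix_(left_idx, posterior.indices)] += bump[None, None, :]

    # shuffle trial order so conditions interleave as in a real session
    order = rng.permutation(n)
    return EpochSet(
        data=data[order],
        fs=params.fs,
        time_ms=time_ms,
        condition=condition[order],
        mirror=mirror[order],
        subject_id=f"S{subject_index:02d}",
        system=system,
        provenance=(
            f"synthetic (seed={params.seed}, subject={subject_index}, "
            f"system={system})"
        ),
    )


def generate_study(params: SyntheticParams) -> dict:
    """All subject x system blocks, keyed by ``(subject_id, system)``."""
    out = {}
    for s in range(params.n_subjects):
        for system in params.systems:
            es = generate_subject(params, s, system)
            out[(es.subject_id, system)] = es
    return out
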