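"""Single-subject bootstrap significance testing.

The resampling unit is the trial: each trial is reduced to a scalar score
(cluster-and-window mean amplitude), the observed effect is the difference
of condition means, and the null distribution is built by pooling all
trials and re-drawing pseudo-high and pseudo-low samples *with
replacement* (50 000 repetitions by default).  The p-value is the
proportion of replicate differences equal to or more extreme than the
observed difference — no continuity correction, so "0 of 50 000 extreme"
maps exactly to p < 0.00002.

Significance is graded across an ordered list of p-criteria
(0.05, 0.025, 0.01, 0.001, 0.00002 by default) with strict inequality:
at B = 50 000 these correspond to fewer than 2500, 1250, 500, 50 and 0
extreme replicates.

Two window policies exist for adaptive scoring: ``fixed_observed`` (the
default — the window adapted to the observed data is reused in every
replicate; this is what inflates null rejection rates) and
``reselect_per_replicate`` (the window search is repeated inside each
replicate), provided for methodological comparison.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet
from .preprocess import compute_erp, erp_difference
from .scoring import (ComponentSpec, SensorCluster, score_component,
                      sliding_window_means, window_length_samples)

DEFAULT_CRITERIA = (0.05, 0.025, 0.01, 0.001, 0.00002)

# amplitude differences are rounded to this grain before the
# "equal or more extreme" comparison, so exact ties in constructed data
# survive floating-point noise
EXTREME_TOL_UV = 1e-9

PERCENTILES = (1.0, 5.0, 25.0, 50.0, 75.0, 95.0, 99.0)


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 50_000
    seed: int = 0
    sidedness: str = "one"  # "one" | "two"
    criteria: tuple = DEFAULT_CRITERIA
    window_policy: str = "fixed_observed"  # or "reselect_per_replicate"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        crit = tuple(self.criteria)
        if any(not (0 < a < 1) for a in crit):
            raise ValueError("criteria must lie in (0, 1)")
        if any(b >= a for a, b in zip(crit, crit[1:])):
            raise ValueError("criteria must be strictly decreasing")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")
        if self.window_policy not in ("fixed_observed", "reselect_per_replicate"):
            raise ValueError("unknown window_policy")


@dataclass
class CaseResult:
    """Outcome of one subject x system x component bootstrap test."""

    subject_id: str
    system: str
    component: str
    observed_difference: float
    window_used: tuple
    mode: str
    p_one_sided: float
    p_two_sided: float
    extreme_count: int
    n_boot: int
    significance_flags: dict
    distribution_summary: dict
    n_trials: int = 0

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "system": self.system,
            "component": self.component,
            "observed_difference": self.observed_difference,
            "window_start_ms": self.window_used[0],
            "window_end_ms": self.window_used[1],
            "mode": self.mode,
            "p_one_sided": self.p_one_sided,
            "p_two_sided": self.p_two_sided,
            "extreme_count": self.extreme_count,
            "n_boot": self.n_boot,
            "n_trials": self.n_trials,
        }
        for alpha, flag in self.significance_flags.items():
            row[f"sig_p{alpha:g}"] = bool(flag)
        return row


def child_seed(root_seed: int, *labels) -> np.random.SeedSequence:
    """Counter-based child seed from stable label hashes, so re-running a
    single case reproduces its slice of a study-level run."""
    keys = [zlib.crc32(str(lab).encode()) for lab in labels]
    return np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, *keys])


# -- per-trial scores -----------------------------------------------------

def per_trial_scores(epochs: EpochSet, cluster: SensorCluster,
                     window: tuple) -> np.ndarray:
    """Scalar score per trial: mean amplitude over cluster sensors and all
    samples inside the (inclusive) window.  Condition means of these
    scores equal the waveform-level component scores exactly."""
    cluster.validate(epochs.n_sensors)
    mask = epochs.time_mask(window[0], window[1])
    if not mask.any():
        raise ValueError(f"window {window} contains no samples")
    return epochs.data[np.ix_(np.arange(epochs.n_trials), cluster.indices,
                              np.flatnonzero(mask))].mean(axis=(1, 2))


# -- the bootstrap --------------------------------------------------------

def bootstrap_distribution(scores_high: np.ndarray, scores_low: np.ndarray,
                           config: BootstrapConfig,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Null distribution of the mean difference under random reassignment.

    Pools the scores; per replicate draws ``n_high`` pseudo-high and
    ``n_low`` pseudo-low values with replacement and records
    mean(pseudo-high) - mean(pseudo-low).
    """
    scores_high = np.asarray(scores_high, dtype=float)
    scores_low = np.asarray(scores_low, dtype=float)
    if scores_high.size == 0 or scores_low.size == 0:
        raise ValueError("both score vectors must be non-empty")
    pooled = np.concatenate([scores_high, scores_low])
    # centering is an identity for the mean difference but keeps the
    # all-identical-scores case at exactly 0; sorting canonicalizes the
    # pool so the replicate stream depends on the scores only through the
    # pooled multiset (trial order cannot leak into the p-value)
    pooled = np.sort(pooled)
    pooled = pooled - pooled.mean()
    n_h, n_l = scores_high.size, scores_low.size
    n = pooled.size
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = np.empty(config.n_boot)
    chunk = max(1, int(4_000_000 // max(n, 1)))
    for lo in range(0, config.n_boot, chunk):
        hi = min(lo + chunk, config.n_boot)
        m = hi - lo
        ih = rng.integers(0, n, size=(m, n_h))
        il = rng.integers(0, n, size=(m, n_l))
        out[lo:hi] = pooled[ih].mean(axis=1) - pooled[il].mean(axis=1)
    return out


def bootstrap_distribution_reselect(
        trial_series: np.ndarray, time_ms: np.ndarray, fs: float,
        n_high: int, spec: ComponentSpec, config: BootstrapConfig,
        rng: np.random.Generator | None = None) -> np.ndarray:
    """Null distribution with the adaptive window search repeated inside
    every replicate.

    ``trial_series`` is the per-trial cluster-mean time series (trials x
    samples) of all pooled trials; per replicate the pseudo-condition mean
    series are formed, and the maximal signed window-mean difference over
    the search range is recorded.
    """
    in_range = (time_ms >= spec.search_range[0]) & (time_ms <= spec.search_range[1])
    series = np.asarray(trial_series, dtype=float)[:, in_range]
    n = series.shape[0]
    n_low = n - n_high
    if n_high < 1 or n_low < 1:
        raise ValueError("need trials in both pseudo-conditions")
    wlen = window_length_samples(spec.span_ms, fs)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = np.empty(config.n_boot)
    chunk = max(1, int(2_000_000 // max(n * series.shape[1], 1)))
    for lo in range(0, config.n_boot, chunk):
        hi = min(lo + chunk, config.n_boot)
        m = hi - lo
        ih = rng.integers(0, n, size=(m, n_high))
        il = rng.integers(0, n, size=(m, n_low))
        diff = series[ih].mean(axis=1) - series[il].mean(axis=1)
        c = np.cumsum(diff, axis=1)
        wmeans = np.empty((m, diff.shape[1] - wlen + 1))
        wmeans[:, 0] = c[:, wlen - 1]
        wmeans[:, 1:] = c[:, wlen:] - c[:, :-wlen]
        wmeans /= wlen
        out[lo:hi] = spec.direction * np.max(spec.direction * wmeans, axis=1)
    return out


def bootstrap_p(observed: float, distribution: np.ndarray, direction: int,
                sidedness: str = "one") -> tuple:
    """(p, extreme_count): proportion of replicates equal to or more
    extreme than the observed difference.

    One-sided: ``direction * d >= direction * observed``; two-sided:
    ``|d| >= |observed|``.  Equality is decided after rounding the
    comparison to EXTREME_TOL_UV.
    """
    d = np.asarray(distribution, dtype=float)
    if d.size == 0:
        raise ValueError("empty bootstrap distribution")
    if sidedness == "one":
        count = int(np.sum(direction * d >= direction * observed - EXTREME_TOL_UV))
    elif sidedness == "two":
        count = int(np.sum(np.abs(d) >= np.abs(observed) - EXTREME_TOL_UV))
    else:
        raise ValueError("sidedness must be 'one' or 'two'")
    return count / d.size, count


def classify_significance(p: float, criteria=DEFAULT_CRITERIA) -> dict:
    """Flag per criterion with strict inequality (p < alpha)."""
    return {float(a): bool(p < a) for a in criteria}


def criterion_count_bound(alpha: float, n_boot: int) -> int:
    """Smallest extreme count that fails the criterion: a test is
    significant iff extreme_count < this bound (e.g. 2500 at alpha=0.05,
    B=50 000)."""
    c = 0
    while classify_significance(c / n_boot, (alpha,))[alpha]:
        c += 1
    return c


# -- whole-case driver ----------------------------------------------------

def run_case_analysis(epochs: EpochSet, specs, config: BootstrapConfig,
                      mode: str = "adaptive") -> list:
    """Bootstrap test of every component on one preprocessed, trial-
    equated EpochSet.  Returns one :class:`CaseResult` per component."""
    if isinstance(specs, dict):
        specs = list(specs.values())
    results = []
    for spec in specs:
        score = score_component(epochs, spec, mode=mode)
        rng = np.random.default_rng(
            child_seed(config.seed, epochs.subject_id, epochs.system, spec.name))
        scores = per_trial_scores(epochs, spec.cluster, score.window_used)
        high = scores[epochs.condition == "high"]
        low = scores[epochs.condition == "low"]
        if mode == "adaptive" and config.window_policy == "reselect_per_replicate":
            mask = epochs.condition == "high"
            series = epochs.data[:, spec.cluster.indices, :].mean(axis=1)
            series = np.concatenate([series[mask], series[~mask]])
            dist = bootstrap_distribution_reselect(
                series, epochs.time_ms, epochs.fs, int(mask.sum()), spec,
                config, rng)
        else:
            dist = bootstrap_distribution(high, low, config, rng)
        p_one, count_one = bootstrap_p(score.difference, dist, spec.direction, "one")
        p_two, count_two = bootstrap_p(score.difference, dist, spec.direction, "two")
        p_used, count_used = (p_one, count_one) if config.sidedness == "one" \
            else (p_two, count_two)
        results.append(CaseResult(
            subject_id=epochs.subject_id,
            system=epochs.system,
            component=spec.name,
            observed_difference=score.difference,
            window_used=score.window_used,
            mode=mode,
            p_one_sided=p_one,
            p_two_sided=p_two,
            extreme_count=count_used,
            n_boot=config.n_boot,
            significance_flags=classify_significance(p_used, config.criteria),
            distribution_summary={
                f"p{q:g}": float(np.percentile(dist, q)) for q in PERCENTILES
            },
            n_trials=epochs.n_trials,
        ))
    return results


def split_halves(epochs: EpochSet) -> tuple:
    """First/second-half split by original trial order within each
    condition (habituation control).  Odd counts give the extra trial to
    the first half."""
    first = np.zeros(epochs.n_trials, dtype=bool)
    for cond in np.unique(epochs.condition):
        idx = np.flatnonzero(epochs.condition == cond)
        if idx.size < 2:
            raise ValueError(f"need >= 2 trials per condition, {cond!r} has {idx.size}")
        first[idx[: (idx.size + 1) // 2]] = True
    return (epochs.subset(np.flatnonzero(first), note="first half"),
            epochs.subset(np.flatnonzero(~first), note="second half"))
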