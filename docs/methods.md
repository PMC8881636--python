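# Methods

## The case-level bootstrap test

The unit of inference is one participant × behavior-system block of
epoched EEG (−100…800 ms around picture onset, 250 Hz).  A component score
reduces each trial to a scalar: the mean amplitude over the component's
sensor cluster and a time window (inclusive endpoints; at 250 Hz a 60-ms
window holds `round(60·fs/1000)+1 = 16` samples).  The observed effect is
the difference of condition mean scores, identical whether computed from
condition-average waveforms or from per-trial scores (linearity of the
mean).

The null distribution pools all trial scores and, per replicate, draws
`n_high` pseudo-high and `n_low` pseudo-low scores *with replacement*,
recording the mean difference.  The one-sided p is the proportion of
replicates equal to or more extreme than the observed difference in the
component's expected direction (EPN negative, LPP positive); "equal" is
decided after rounding the comparison at 10⁻⁹ µV so exact ties in
constructed data survive floating-point noise.  No continuity correction
is applied (`p = count/B`), so at B = 50 000 the graded criteria
P < 0.05 / 0.025 / 0.01 / 0.001 / 0.00002 are exactly "fewer than
2500 / 1250 / 500 / 50 / 0 extreme replicates".  Significance is strict
(`p < α`).

Internally the pooled scores are sorted and centered before resampling.
Both are identities for the statistic, but they make the replicate stream
a function of the pooled *multiset* alone — trial order cannot leak into
the p-value — and keep the degenerate all-identical-scores case at exactly
zero.

### Window adaptation and its cost

In adaptive mode the scoring window is the span-length window inside the
component's search range (EPN: 60 ms in 150–350 ms; LPP: 100 ms in
350–750 ms) maximizing the signed cluster-mean difference, slid in
1-sample steps, earliest start on ties.  The search operates on the
cluster-mean difference series, matching the cluster-mean scoring used
everywhere else.

Under the default `window_policy="fixed_observed"` the window adapted to
the observed data is reused in every bootstrap replicate.  The observed
statistic is then a maximum over ~36 (EPN) or ~76 (LPP) overlapping
windows while the null replicates are not, so the null test is
anticonservative by construction: in our calibration runs (500 null
subjects, 16 sensors, 100 trials/condition, B = 2000) the fixed-window
test rejects at ≈ 5% while the adaptive test rejects at ≈ 14% — the
mechanism behind elevated mirror-split false-alarm rates at P < 0.05.
`reselect_per_replicate` repeats the window search inside every replicate
and is provided for methodological comparison; it restores a
maximum-vs-maximum comparison at roughly the windows-count-fold cost.

## Preprocessing

Butterworth band limiting (40 Hz low-pass of order 19 and 0.06 Hz
high-pass of order 4, half-power cutoffs) is realized as cascaded
second-order sections; the contract is the magnitude response (−3.01 dB at
each cutoff per pass), not a coefficient layout.  Filtering defaults to
zero-phase (forward–backward) application because scoring uses window
means, where a causal phase delay would bias latencies; causal mode is
retained for fidelity experiments.  Whether the original chain filtered
causally was not determinable, hence the switch.

Baseline adjustment (per-trial, per-sensor mean over the half-open
[−100, 0) ms interval) precedes average referencing.  The order was a
genuinely open choice; baseline-first makes both identities hold
simultaneously afterwards (zero baseline mean per trial/sensor *and* zero
across-sensor sum per sample), and the two orders differ only by a
per-trial constant shared across sensors, which the average reference
removes from every score.

Artifact rejection is a deliberate simplification: trials with any
|amplitude| > 100 µV are dropped and logged.  The statistically controlled
rejection used with dense-net recordings is out of scope; the rule here
only needs to protect the resampling pool from gross outliers.  Trial
counts are then equated between conditions by seeded random subsampling of
the larger condition (order-preserving), so both conditions contribute
equally to the pooled null.

Note that the average reference attenuates a cluster-confined effect by
(1 − q/n_sensors) for a q-sensor cluster; with the full 256-sensor layout
this is ~16% (41/256), with reduced simulation layouts proportionally
more.  Experiments that need a *realized* effect size (e.g. the 4-SE power
run) therefore calibrate against a noise-free pilot subject passed through
the same preprocessing rather than against the raw template amplitude.

## Signal-quality gates

The (±) reference averages trials with alternating polarity (+, −, +, …
in original order, divisor = trial count), cancelling the stimulus-locked
signal exactly for an even number of identical trials and leaving a
noise-level estimate comparable to the regular average (both are σ/√n
estimators).

The bootstrap SNR draws, per replicate, `n_min` trials with replacement
from *each* condition (`n_min` = the smaller condition count), averages
them, and computes `20·log10(RMS_post / RMS_pre)` of the cluster-mean
waveform — the amplitude-ratio convention, equal to `10·log10` of the
power ratio.  Pre-stimulus is [−100, 0) ms; post-stimulus defaults to the
full (0, epoch-end] interval since no narrower extent is prescribed.  The
case passes if the lower bound of the central 90% percentile interval
reaches 3 dB.  Drawing `n_min` per condition (rather than `n_min` from the
pooled trials) keeps both categories equally represented and makes the
replicate average the same kind of estimator as the reported ERP; with the
pooled reading the replicates average half as many trials as the estimate
and the nominal 90% interval covers a known ratio essentially always
(~99–100% in our simulations) instead of ≈ 90%.

## Specificity analysis

Left- and right-mirrored presentations of the same pictures are a built-in
null contrast.  Within each picture category the mirror labels become
pseudo-conditions (left → high, right → low), counts are equated, and the
component is scored and bootstrap-tested with the main-analysis parameters
in both directions — four tests per case and component.  With fixed
windows the two directions share one bootstrap distribution (the statistic
merely changes sign); in adaptive mode the window is re-selected per
direction (maximizing that direction's signed difference), so each
direction carries its own distribution.  The false-alarm rate is the
percentage of significant null tests per system × component × criterion.

## Group statistics

Paired t-tests operate on the fixed-window scores (one difference per
subject); Cohen's d is mean(diff)/sd(diff), consistent with reporting
t = M/(s.d./√n) quadruples.  Cochran-Q (via statsmodels) tests equality of
the proportion of significant cases across p-criteria or across systems;
when every row is constant the 0/0 statistic is read as Q = 0, p = 1 (no
evidence of any difference — the common ceiling-effect case).  Post hocs
are pairwise exact McNemar tests with Bonferroni adjustment; the exact
McNemar p is the two-sided binomial tail on the discordant counts, with
b = c = 0 ⇒ p = 1 by convention.  Table percentages round to the nearest
integer with ties away from zero (15/16 → 94, 14/16 → 88).

## The synthetic generator

Per-trial additive model: spatially correlated 1/f^β noise +
condition-independent evoked shape + condition-dependent effect bumps.

* **Noise.** A shared all-sensor power-law series and sensor-independent
  series mixed as `√ρ·shared + √(1−ρ)·independent`, each built in the
  frequency domain (complex-Gaussian coefficients with amplitude
  f^(−β/2), DC and Nyquist zeroed) and normalized so every sensor's
  marginal SD is `noise_sd` exactly in expectation.  The spatial
  coherence ρ (default 0.3) exists because cluster-mean standard errors —
  which the whole analysis stands on — are unrealistically small with
  independent sensors.
* **Evoked shape.** A positive Hann bump on the posterior cluster and a
  negative one on the central cluster (default 4 µV), matching the
  polarity of real posterior/central ERPs; it gives the SNR gate genuine
  post-stimulus signal.
* **Effects.** Hann windows of the component's span (EPN 60 ms at 270 ms,
  LPP 100 ms at 450 ms) added to high-arousal trials on the component's
  cluster — smooth, compactly supported and analytically integrable, so
  zero-noise closed-form oracles exist.  Per-trial amplitude jitter
  (1 µV), latency jitter (20 ms), and per-subject lognormal scale factors
  (σ = 0.47, shared across systems per component) emulate trial and
  individual variation.
* **Mirror labels** are balanced within condition and carry no signal by
  default; `mirror_effect_amp` can inject an EPN-shaped left-trial bump
  to exercise specificity power.
* **Seeding** is counter-based: child seeds derive from
  (seed, subject, system) and, in the analysis layer, from stable hashes
  of (subject, system, component), so any single case reproduces its
  slice of a study-level run.

Default effect peak amplitudes are twice the group-mean differences
reported for the three systems (a Hann bump's mean weight over its support
is ≈ 0.5), and `noise_sd` = 20 µV was chosen once so that group-level
Cohen's d ≈ 2 is attainable at the design trial count — the published
range is d ≈ 1.7–2.5.  Single-trial noise magnitudes are not published, so
*case-level* sensitivity in the synthetic study is not calibrated to the
published tables: with the reduced 16-sensor layout (4-sensor clusters)
the weaker systems sit closer to the detection threshold and synthetic
sensitivities fall below the published ones, while the qualitative
structure — ordering of systems, decline across stricter criteria,
adaptive ≥ fixed sensitivity, false alarms ≈ 11–16% at P < 0.05 shrinking
to ~0 at stricter criteria — reproduces.  What passing tests show is that
the *pipeline's statistical mechanics* are right (calibration, inflation,
power, coverage, enumeration agreement), not that the generator matches
real recordings; it omits ocular artifacts, bad channels, non-stationary
noise, and any EPN–LPP coupling across subjects (the components' scale
factors are independent, so the generator does not emulate the negative
EPN–LPP correlation seen in real data).

## Problem sizes

Simulation experiments run at reduced sizes chosen once: 16 sensors
(clusters = contiguous quarters of the array), B = 2000 bootstrap
replicates, 100 trials/condition for null calibration (500 subjects) and
the full 600 trials/condition for the power run (100 subjects) and the
study drivers (16 subjects × 3 systems).  The statistical properties under
test — type-I rate, inflation, coverage, power at a given SE multiple —
do not depend on the full 256-sensor, 50 000-replicate design, which the
defaults nevertheless implement.

## Known limitations

* The adaptive-window inflation magnitude depends on the noise spectrum
  (smoother noise → fewer effectively independent windows); the ≈ 14%
  figure is specific to 1/f noise at these sizes.
* `reselect_per_replicate` is O(windows) slower and is exercised only at
  small sizes.
* The artifact rejector is amplitude-only; it cannot emulate
  sensor-specific statistical control.
* FIF round trips pass through float32 (MNE's storage), so equality holds
  to ~10⁻³ µV, not bitwise.
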