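"""The single-subject bootstrap: distributions, p-values, grading."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_epochs
from erpcase.casestats import (BootstrapConfig, bootstrap_distribution,
                               bootstrap_p, classify_significance,
                               criterion_count_bound, per_trial_scores,
                               run_case_analysis, split_halves)
from erpcase.scoring import SensorCluster, default_component_specs
from erpcase.simulate import generate_subject


class TestPerTrialScores:
    def test_constant_trial(self):
        ep = make_epochs(np.full((2, 2, 226), 5.0))
        scores = per_trial_scores(ep, SensorCluster("c", (0, 1)), (240, 300))
        assert np.all(scores == 5.0)

    def test_condition_means_equal_component_scores(self, rng):
        from erpcase.scoring import score_component
        ep = make_epochs(rng.normal(size=(12, 8, 226)))
        spec = default_component_specs(8)["LPP"]
        score = score_component(ep, spec, mode="fixed")
        s = per_trial_scores(ep, spec.cluster, spec.fixed_window)
        assert s[ep.condition == "high"].mean() == pytest.approx(
            score.mean_high, abs=1e-12)
        assert s[ep.condition == "low"].mean() == pytest.approx(
            score.mean_low, abs=1e-12)

    def test_matches_bruteforce_loop(self, rng):
        ep = make_epochs(rng.normal(size=(4, 3, 226)))
        cluster = SensorCluster("c", (0, 2))
        scores = per_trial_scores(ep, cluster, (100, 200))
        cols = np.flatnonzero((ep.time_ms >= 100) & (ep.time_ms <= 200))
        for i in range(4):
            vals = [ep.data[i, s, c] for s in (0, 2) for c in cols]
            assert scores[i] == pytest.approx(np.mean(vals), abs=1e-12)


class TestBootstrapDistribution:
    def test_identical_scores_give_zero_differences(self):
        cfg = BootstrapConfig(n_boot=200, seed=1)
        dist = bootstrap_distribution(np.full(5, 3.3), np.full(7, 3.3), cfg)
        assert np.all(dist == 0.0)

    def test_symmetric_pooled_scheme_centers_on_zero(self):
        cfg = BootstrapConfig(n_boot=50_000, seed=2)
        scores = np.array([1.0, 2.0, 3.0])
        dist = bootstrap_distribution(scores, scores, cfg)
        # MC standard error of the replicate mean difference
        pooled_var = np.mean((scores - scores.mean()) ** 2)
        mc_se = np.sqrt(2 * pooled_var / 3 / cfg.n_boot)
        assert abs(dist.mean()) < 3 * mc_se

    def test_matches_exhaustive_enumeration_cdf(self):
        """3+3 trials: the empirical CDF at B = 50 000 stays within 0.01
        (sup norm) of the exact with-replacement enumeration."""
        high = np.array([0.3, 1.1, 2.0])
        low = np.array([-0.5, 0.2, 0.9])
        pooled = np.concatenate([high, low])
        exact = np.sort([
            np.mean(h) - np.mean(l)
            for h in itertools.product(pooled, repeat=3)
            for l in itertools.product(pooled, repeat=3)
        ])
        cfg = BootstrapConfig(n_boot=50_000, seed=3)
        dist = bootstrap_distribution(high, low, cfg)
        # merge float-duplicate atoms before comparing the discrete CDFs
        exact = np.sort(np.round(exact, 9))
        dist = np.sort(np.round(dist, 9))
        grid = np.unique(exact)
        cdf_exact = np.searchsorted(exact, grid, side="right") / exact.size
        cdf_boot = np.searchsorted(dist, grid, side="right") / dist.size
        assert np.max(np.abs(cdf_exact - cdf_boot)) < 0.01

    def test_deterministic_for_seed(self):
        cfg = BootstrapConfig(n_boot=1000, seed=9)
        a = bootstrap_distribution(np.arange(4.0), np.arange(3.0), cfg)
        b = bootstrap_distribution(np.arange(4.0), np.arange(3.0), cfg)
        assert np.array_equal(a, b)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_depends_only_on_pooled_multiset_and_counts(self, seed):
        """Swapping scores between the groups (same counts) leaves the
        null distribution unchanged."""
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=8)
        cfg = BootstrapConfig(n_boot=500, seed=seed)
        a = bootstrap_distribution(scores[:5], scores[5:], cfg)
        perm = rng.permutation(8)
        b = bootstrap_distribution(scores[perm][:5], scores[perm][5:], cfg)
        assert np.array_equal(a, b)


class TestBootstrapP:
    def test_equality_counts_as_extreme(self):
        p, count = bootstrap_p(0.0, np.zeros(100), direction=1)
        assert p == 1.0 and count == 100

    def test_forty_nine_extreme_of_fifty_thousand(self):
        """49 extreme replicates of 50 000: p = 0.00098, significant at
        P < 0.001 but not at P < 0.00002."""
        dist = np.concatenate([np.full(49, 5.0), np.full(49_951, -5.0)])
        p, count = bootstrap_p(2.0, dist, direction=1)
        assert count == 49 and p == pytest.approx(0.00098)
        flags = classify_significance(p)
        assert flags[0.001] and not flags[0.00002]

    def test_observed_beyond_all_replicates(self):
        rng = np.random.default_rng(0)
        p, count = bootstrap_p(99.0, rng.normal(size=1000), direction=1)
        assert p == 0.0 and count == 0
        assert all(classify_significance(p).values())

    def test_two_sided_counts_absolute_values(self):
        dist = np.array([-3.0, -1.0, 0.5, 2.0, 4.0])
        p, count = bootstrap_p(-2.0, dist, direction=-1, sidedness="two")
        assert count == 3  # -3, 2, 4


class TestClassifySignificance:
    def test_graded_flags(self):
        flags = classify_significance(0.0009)
        assert flags == {0.05: True, 0.025: True, 0.01: True,
                         0.001: True, 0.00002: False}

    def test_boundary_is_strict(self):
        assert not any(classify_significance(0.05).values())

    def test_count_bounds_at_fifty_thousand(self):
        """Exclusive extreme-count bounds at B = 50 000 for the five
        graded criteria: 2500, 1250, 500, 50 and 0 (a single extreme
        replicate already fails the strictest criterion)."""
        bounds = [criterion_count_bound(a, 50_000)
                  for a in (0.05, 0.025, 0.01, 0.001, 0.00002)]
        assert bounds == [2500, 1250, 500, 50, 1]

    @given(st.floats(0, 1, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_flags_nested_across_criteria(self, p):
        flags = list(classify_significance(p).values())
        # once a looser criterion fails, all stricter ones fail
        assert flags == sorted(flags, reverse=True)


class TestRunCaseAnalysis:
    def test_zero_noise_large_effect_p_zero(self, quiet_params):
        import dataclasses
        p = dataclasses.replace(quiet_params, trial_amp_sd=0.01,
                                n_trials_per_condition=20)
        ep = generate_subject(p, 0, "sexual_reproduction")
        specs = default_component_specs(p.n_sensors)
        cfg = BootstrapConfig(n_boot=2000, seed=4)
        for res in run_case_analysis(ep, specs, cfg, mode="adaptive"):
            assert res.p_one_sided == 0.0
            assert res.extreme_count == 0
            assert all(res.significance_flags.values())

    def test_p_invariant_to_trial_relabeling(self, small_params, rng):
        ep = generate_subject(small_params, 1, "disease_avoidance")
        specs = default_component_specs(small_params.n_sensors)
        cfg = BootstrapConfig(n_boot=1000, seed=5)
        a = run_case_analysis(ep, specs, cfg)
        b = run_case_analysis(ep.subset(rng.permutation(ep.n_trials)),
                              specs, cfg)
        for ra, rb in zip(a, b):
            assert ra.p_one_sided == rb.p_one_sided

    def test_one_and_two_sided_agree_for_predicted_direction(self,
                                                             small_params):
        """Effects in the predicted direction: the P < 0.05 verdict is the
        same one- and two-sided (as observed in the main analysis)."""
        import dataclasses
        p = dataclasses.replace(small_params, n_trials_per_condition=200,
                                noise_sd=5.0)
        specs = default_component_specs(p.n_sensors)
        cfg = BootstrapConfig(n_boot=2000, seed=6)
        for s in range(3):
            ep = generate_subject(p, s, "sexual_reproduction")
            for res in run_case_analysis(ep, specs, cfg):
                assert ((res.p_one_sided < 0.05)
                        == (res.p_two_sided < 0.05))

    def test_monotone_in_effect_shift(self):
        """Adding a constant to the high-condition scores moves the
        one-sided p in the predicted direction."""
        rng = np.random.default_rng(7)
        high = rng.normal(size=30)
        low = rng.normal(size=30)
        cfg = BootstrapConfig(n_boot=5000, seed=8)
        ps = []
        for shift in (0.0, 0.5, 1.0):
            dist = bootstrap_distribution(high + shift, low, cfg)
            p, _ = bootstrap_p((high + shift).mean() - low.mean(), dist, +1)
            ps.append(p)
        assert ps[0] >= ps[1] >= ps[2]

    def test_reselect_policy_shifts_null_quantiles_outward(self, rng):
        """Re-running the window search inside each replicate widens the
        null distribution relative to reusing the observed window."""
        ep = make_epochs(rng.normal(0, 5, size=(40, 8, 226)))
        specs = [default_component_specs(8)["EPN"]]
        fixed_cfg = BootstrapConfig(n_boot=800, seed=9,
                                    window_policy="fixed_observed")
        res_cfg = BootstrapConfig(n_boot=800, seed=9,
                                  window_policy="reselect_per_replicate")
        r_fixed = run_case_analysis(ep, specs, fixed_cfg, mode="adaptive")[0]
        r_res = run_case_analysis(ep, specs, res_cfg, mode="adaptive")[0]
        assert (r_res.distribution_summary["p5"]
                < r_fixed.distribution_summary["p5"])


class TestSplitHalves:
    def test_balanced_600_gives_300_300(self, rng):
        cond = np.array(["high"] * 600 + ["low"] * 600, dtype=object)
        ep = make_epochs(rng.normal(size=(1200, 1, 5)), fs=1000.0, t0=-1.0,
                         condition=cond)
        first, second = split_halves(ep)
        assert first.condition_counts() == {"high": 300, "low": 300}
        assert second.condition_counts() == {"high": 300, "low": 300}

    def test_odd_counts_favor_first_half(self, rng):
        cond = np.array(["high"] * 5 + ["low"] * 4, dtype=object)
        ep = make_epochs(rng.normal(size=(9, 1, 5)), fs=1000.0, t0=-1.0,
                         condition=cond)
        first, second = split_halves(ep)
        assert first.condition_counts() == {"high": 3, "low": 2}
        assert second.condition_counts() == {"high": 2, "low": 2}

    def test_halves_partition_the_trials(self, noisy_epochs):
        first, second = split_halves(noisy_epochs)
        union = np.concatenate([first.data, second.data])
        assert union.shape == noisy_epochs.data.shape
        rows = {tuple(r) for r in noisy_epochs.data[:, 0, :5]}
        assert {tuple(r) for r in union[:, 0, :5]} == rows

    def test_too_few_trials_rejected(self, rng):
        cond = np.array(["high", "low"], dtype=object)
        ep = make_epochs(rng.normal(size=(2, 1, 5)), fs=1000.0, t0=-1.0,
                         condition=cond)
        with pytest.raises(ValueError):
            split_halves(ep)
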