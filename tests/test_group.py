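"""Group statistics, tables, and the study driver."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from erpcase.casestats import BootstrapConfig, CaseResult, classify_significance
from erpcase.group import (StudyConfig, cochran_q, correlate_components,
                           mcnemar_exact, paired_t_cohens_d, round_percent,
                           run_study, sensitivity_table)
from erpcase.simulate import SyntheticParams


def vector_with_moments(n, mean, sd, seed=0):
    x = np.random.default_rng(seed).normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestPairedT:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            paired_t_cohens_d(np.full(5, 2.0), np.zeros(5))

    def test_reported_convention_for_group_epn(self):
        """n = 16 differences with M = -2.80, s.d. = 1.44 reproduce the
        conventional t = M/(s.d./4) and d = M/s.d. quadruple."""
        diffs = vector_with_moments(16, -2.80, 1.44)
        t, df, p, d = paired_t_cohens_d(diffs, np.zeros(16))
        assert df == 15
        assert t == pytest.approx(-2.80 / (1.44 / 4.0), rel=1e-10)
        assert d == pytest.approx(-2.80 / 1.44, rel=1e-10)
        assert p < 0.001

    def test_matches_textbook_formula_oracle(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        t, df, p, d = paired_t_cohens_d(a, b)
        diff = a - b
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(10))
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1), abs=1e-10)


class TestCochranQ:
    def test_identical_columns_no_difference(self):
        x = np.tile(np.array([[1], [0], [1], [1]]), (1, 3))
        res = cochran_q(x)
        assert res["Q"] == 0.0 and res["p"] == 1.0

    def test_matches_defining_formula(self):
        x = np.array([[1, 1, 0], [1, 0, 0], [1, 1, 1], [0, 1, 0],
                      [1, 0, 0], [1, 1, 0]])
        res = cochran_q(x)
        k = 3
        col = x.sum(axis=0)
        row = x.sum(axis=1)
        q_hand = (k * (k - 1) * np.sum((col - col.mean()) ** 2)
                  / (k * row.sum() - np.sum(row ** 2)))
        assert res["Q"] == pytest.approx(q_hand, abs=1e-10)
        assert res["df"] == 2

    def test_row_permutation_invariant(self, rng):
        x = (rng.uniform(size=(12, 4)) < 0.5).astype(int)
        a = cochran_q(x)["Q"]
        b = cochran_q(x[rng.permutation(12)])["Q"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_posthoc_is_bonferroni_mcnemar(self):
        x = np.array([[1, 0], [1, 0], [1, 0], [1, 1], [0, 0], [1, 0]])
        res = cochran_q(x)
        b = int(np.sum((x[:, 0] == 1) & (x[:, 1] == 0)))
        c = int(np.sum((x[:, 0] == 0) & (x[:, 1] == 1)))
        assert res["posthoc_bonferroni"][(0, 1)] == pytest.approx(
            mcnemar_exact(b, c), abs=1e-12)  # single pair: factor 1


class TestMcNemar:
    def test_symmetric_discordance_gives_one(self):
        assert mcnemar_exact(4, 4) == 1.0

    def test_exact_binomial_tail(self):
        # 2 * P(X <= 1 | n = 8, 1/2) = 18/256
        assert mcnemar_exact(1, 7) == pytest.approx(18.0 / 256.0, abs=1e-12)

    def test_no_discordant_pairs_gives_one(self):
        assert mcnemar_exact(0, 0) == 1.0

    def test_agrees_with_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        table = [[10, 3], [9, 5]]
        expected = sm_mcnemar(table, exact=True).pvalue
        assert mcnemar_exact(3, 9) == pytest.approx(expected, abs=1e-12)


class TestRounding:
    @pytest.mark.parametrize("k,n,expected", [
        (14, 16, 88), (15, 16, 94), (16, 16, 100), (1, 8, 13), (1, 2, 50),
    ])
    def test_nearest_percent_ties_away_from_zero(self, k, n, expected):
        assert round_percent(k, n) == expected


class TestCorrelation:
    def test_perfect_negative(self):
        x = np.arange(5.0)
        r, _ = correlate_components(x, -x)
        assert r == pytest.approx(-1.0, abs=1e-12)

    def test_independent_data_near_zero(self, rng):
        r, _ = correlate_components(rng.normal(size=1000),
                                    rng.normal(size=1000))
        assert abs(r) < 0.1

    def test_matches_formula_oracle(self, rng):
        x, y = rng.normal(size=16), rng.normal(size=16)
        r, _ = correlate_components(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = np.sum(xc * yc) / np.sqrt(np.sum(xc ** 2) * np.sum(yc ** 2))
        assert r == pytest.approx(r_hand, abs=1e-10)


def _fake_case(subject, system, component, p):
    return CaseResult(
        subject_id=subject, system=system, component=component,
        observed_difference=-1.0, window_used=(240.0, 300.0),
        mode="adaptive", p_one_sided=p, p_two_sided=min(1.0, 2 * p),
        extreme_count=int(p * 1000), n_boot=1000,
        significance_flags=classify_significance(p),
        distribution_summary={}, n_trials=100)


class TestSensitivityTable:
    def test_percentages_match_printed_convention(self):
        results = [
            _fake_case(f"S{i:02d}", "sys", "EPN",
                       0.001 if i < 14 else 0.5)
            for i in range(16)
        ]
        table = sensitivity_table(results, (0.05,))
        assert table.loc[0, "p<0.05"] == 88  # 14 of 16
        results[14] = _fake_case("S14", "sys", "EPN", 0.001)
        assert sensitivity_table(results, (0.05,)).loc[0, "p<0.05"] == 94
        results[15] = _fake_case("S15", "sys", "EPN", 0.001)
        assert sensitivity_table(results, (0.05,)).loc[0, "p<0.05"] == 100

    def test_sensitivity_non_increasing_across_criteria(self, rng):
        criteria = (0.05, 0.025, 0.01, 0.001, 0.00002)
        results = [_fake_case(f"S{i:02d}", "sys", "LPP",
                              float(rng.uniform(0, 0.1)))
                   for i in range(16)]
        table = sensitivity_table(results, criteria)
        rates = [table.loc[0, f"p<{a:g}"] for a in criteria]
        assert rates == sorted(rates, reverse=True)


@pytest.fixture(scope="module")
def tiny_study_report():
    params = SyntheticParams(
        n_subjects=3, n_sensors=8, n_trials_per_condition=24,
        systems=("sexual_reproduction", "predator_fear"), noise_sd=3.0,
        seed=21)
    config = StudyConfig(
        params=params,
        bootstrap=BootstrapConfig(n_boot=400, seed=21),
        filter_spec=None,
        snr=None,
    )
    return config, run_study(config)


class TestRunStudy:
    def test_report_covers_all_strata(self, tiny_study_report):
        _, report = tiny_study_report
        assert set(report.sensitivity_adaptive["system"]) == {
            "sexual_reproduction", "predator_fear"}
        assert set(report.sensitivity_adaptive["component"]) == {"EPN", "LPP"}
        assert len(report.case_results) == 3 * 2 * 2
        # four specificity tests per case and component
        assert len(report.specificity_results) == 3 * 2 * 2 * 4

    def test_tables_recompute_from_case_rows(self, tiny_study_report):
        config, report = tiny_study_report
        again = sensitivity_table(report.case_results,
                                  config.bootstrap.criteria)
        pd.testing.assert_frame_equal(report.sensitivity_adaptive, again)

    def test_rerun_is_deterministic(self, tiny_study_report):
        config, report = tiny_study_report
        report2 = run_study(config)
        pd.testing.assert_frame_equal(report.case_results,
                                      report2.case_results)
        pd.testing.assert_frame_equal(report.false_alarms,
                                      report2.false_alarms)

    def test_write_produces_standard_files(self, tiny_study_report, tmp_path):
        _, report = tiny_study_report
        report.write(tmp_path)
        for name in ("case_results.csv", "sensitivity_table.csv",
                     "false_alarm_table.csv", "specificity.csv",
                     "group_stats.json", "qc.csv"):
            assert (tmp_path / name).exists()

    def test_snr_gate_excludes_hopelessly_noisy_studies(self):
        """When no case clears the 3 dB lower-bound gate the study run
        aborts with a QC-referencing error instead of silently producing
        empty tables."""
        params = SyntheticParams(
            n_subjects=2, n_sensors=8, n_trials_per_condition=12,
            systems=("predator_fear",), noise_sd=40.0, seed=22)
        config = StudyConfig(params=params,
                             bootstrap=BootstrapConfig(n_boot=200, seed=22),
                             filter_spec=None, artifact_threshold=None,
                             run_specificity=False, run_halves=False)
        with pytest.raises(ValueError, match="quality gate"):
            run_study(config)
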