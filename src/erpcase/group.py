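"""Group-level statistics and study orchestration.

Provides the conventional group tests that frame the case-by-case
results — paired t with Cohen's d (mean of paired differences over their
SD), Cochran-Q over proportions of significant cases with pairwise exact
McNemar post hocs (Bonferroni), exact McNemar for the first/second-half
habituation comparison, and the EPN-LPP magnitude correlation — plus the
sensitivity/false-alarm tables across p-criteria and the ``run_study``
driver that executes the whole pipeline on a synthetic study.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import cochrans_q as _sm_cochrans_q

from .casestats import (BootstrapConfig, child_seed, run_case_analysis,
                        split_halves)
from .preprocess import FilterSpec, preprocess
from .quality import SnrConfig, snr_ci
from .scoring import default_component_specs
from .simulate import SyntheticParams, generate_subject
from .specificity import false_alarm_table, results_frame, run_specificity


def round_percent(k: int, n: int) -> int:
    """Nearest-integer percent, ties away from zero (15/16 -> 94,
    14/16 -> 88)."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    return int(math.floor(100.0 * k / n + 0.5))


# -- classical tests ------------------------------------------------------

def paired_t_cohens_d(values_a, values_b) -> tuple:
    """(t, df, p_two_sided, d) for paired samples; d = mean(diff)/sd(diff)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = a - b
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("paired differences have zero variance")
    res = stats.ttest_rel(a, b)
    return (float(res.statistic), a.size - 1, float(res.pvalue),
            float(diff.mean() / sd))


def cochran_q(binary_matrix) -> dict:
    """Cochran's Q over a subjects x conditions binary matrix, with
    pairwise exact McNemar post hocs (Bonferroni-adjusted)."""
    x = np.asarray(binary_matrix)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 conditions")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("entries must be binary")
    k = x.shape[1]
    row_sums = x.sum(axis=1)
    if not np.any((row_sums > 0) & (row_sums < k)):
        # every row constant => all columns identical; no evidence of any
        # difference between conditions (the 0/0 limit is read as Q = 0)
        return {"Q": 0.0, "df": k - 1, "p": 1.0,
                "posthoc_bonferroni": {(i, j): 1.0 for i in range(k)
                                       for j in range(i + 1, k)}}
    res = _sm_cochrans_q(x, return_object=True)
    n_pairs = k * (k - 1) // 2
    posthoc = {}
    for i in range(k):
        for j in range(i + 1, k):
            b = int(np.sum((x[:, i] == 1) & (x[:, j] == 0)))
            c = int(np.sum((x[:, i] == 0) & (x[:, j] == 1)))
            posthoc[(i, j)] = min(1.0, mcnemar_exact(b, c) * n_pairs)
    return {
        "Q": float(res.statistic),
        "df": k - 1,
        "p": float(res.pvalue),
        "posthoc_bonferroni": posthoc,
    }


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p on discordant-pair counts; b = c = 0
    yields p = 1 by convention."""
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    n = b + c
    if n == 0:
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))


def correlate_components(epn_diffs, lpp_diffs) -> tuple:
    """(r, p): product-moment correlation of per-subject EPN and LPP
    difference magnitudes."""
    x = np.asarray(epn_diffs, dtype=float)
    y = np.asarray(lpp_diffs, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# -- tables ---------------------------------------------------------------

def case_results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def sensitivity_table(case_results, criteria) -> pd.DataFrame:
    """% of subjects significant per system x component x criterion."""
    df = case_results if isinstance(case_results, pd.DataFrame) \
        else case_results_frame(case_results)
    if len(df) == 0:
        raise ValueError("no case results")
    rows = []
    for (system, component), grp in df.groupby(["system", "component"], sort=False):
        row = {"system": system, "component": component}
        for alpha in criteria:
            col = f"sig_p{alpha:g}"
            row[f"p<{alpha:g}"] = round_percent(int(grp[col].sum()), len(grp))
        rows.append(row)
    return pd.DataFrame(rows)


# -- study orchestration --------------------------------------------------

@dataclass
class StudyConfig:
    params: SyntheticParams = field(default_factory=SyntheticParams)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    filter_spec: FilterSpec | None = field(default_factory=FilterSpec)
    artifact_threshold: float | None = 100.0
    snr: SnrConfig | None = None  # defaults to bootstrap-sized SnrConfig
    run_specificity: bool = True
    run_halves: bool = True


@dataclass
class StudyReport:
    sensitivity_adaptive: pd.DataFrame
    sensitivity_fixed: pd.DataFrame
    false_alarms: pd.DataFrame | None
    group_tests: pd.DataFrame
    cochran_criteria: dict
    mcnemar_halves: dict
    correlations: dict
    case_results: pd.DataFrame
    specificity_results: pd.DataFrame | None
    halves_results: pd.DataFrame | None
    qc: pd.DataFrame

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.case_results.to_csv(out / "case_results.csv", index=False)
        self.sensitivity_adaptive.to_csv(out / "sensitivity_table.csv", index=False)
        self.sensitivity_fixed.to_csv(out / "sensitivity_table_fixed.csv", index=False)
        if self.false_alarms is not None:
            self.false_alarms.to_csv(out / "false_alarm_table.csv", index=False)
        if self.specificity_results is not None:
            self.specificity_results.to_csv(out / "specificity.csv", index=False)
        if self.halves_results is not None:
            self.halves_results.to_csv(out / "halves_results.csv", index=False)
        self.group_tests.to_csv(out / "group_stats.csv", index=False)
        self.qc.to_csv(out / "qc.csv", index=False)
        summary = {
            "cochran_criteria": {
                comp: {k: v for k, v in res.items() if k != "posthoc_bonferroni"}
                for comp, res in self.cochran_criteria.items()
            },
            "mcnemar_halves": self.mcnemar_halves,
            "correlations": self.correlations,
        }
        (out / "group_stats.json").write_text(json.dumps(summary, indent=2))


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Execute the full pipeline on a synthetic study.

    Per subject x system: generate, preprocess, SNR-gate, case analysis in
    adaptive and fixed modes, specificity tests, half-split habituation
    reanalysis; then assemble group statistics and the study tables.
    Deterministic for a fixed config.
    """
    params = config.params
    specs = default_component_specs(params.n_sensors)
    spec_list = list(specs.values())
    boot = config.bootstrap
    snr_cfg = config.snr or SnrConfig(n_boot=min(boot.n_boot, 2000),
                                      seed=boot.seed)

    case_rows, fixed_rows, spec_results, halves_rows, qc_rows = [], [], [], [], []
    adaptive_diffs = {}  # (system, component) -> {subject: diff}

    for s in range(params.n_subjects):
        for system in params.systems:
            try:
                raw = generate_subject(params, s, system)
                ep = preprocess(
                    raw, config.filter_spec,
                    artifact_threshold=config.artifact_threshold,
                    equate_seed=child_seed(boot.seed, raw.subject_id, system,
                                           "equate"))
                qc_pass = True
                for cname, spec in specs.items():
                    snr = snr_ci(ep, spec.cluster, snr_cfg)
                    qc_rows.append({
                        "subject_id": ep.subject_id, "system": system,
                        "cluster": spec.cluster.name,
                        "lower_db": snr.lower_db, "upper_db": snr.upper_db,
                        "pass": snr.passed,
                    })
                    qc_pass &= snr.passed
                if not qc_pass:
                    continue  # excluded case (mirrors low-trial exclusions)

                for res in run_case_analysis(ep, spec_list, boot, mode="adaptive"):
                    case_rows.append(res)
                    adaptive_diffs.setdefault((system, res.component), {})[
                        res.subject_id] = res.observed_difference
                for res in run_case_analysis(ep, spec_list, boot, mode="fixed"):
                    fixed_rows.append(res)

                if config.run_specificity:
                    spec_results.extend(run_specificity(ep, spec_list, boot,
                                                        mode="adaptive"))
                if config.run_halves:
                    for half_name, half in zip(("first", "second"),
                                               split_halves(ep)):
                        for res in run_case_analysis(half, spec_list, boot,
                                                     mode="adaptive"):
                            row = res.to_row()
                            row["half"] = half_name
                            halves_rows.append(row)
            except Exception as exc:
                raise RuntimeError(
                    f"study failed at subject S{s:02d}, system {system}: {exc}"
                ) from exc

    criteria = boot.criteria
    if not case_rows:
        raise ValueError(
            "no case passed the SNR quality gate; see the QC table "
            f"({sum(not r['pass'] for r in qc_rows)} failing cluster checks)")
    case_df = case_results_frame(case_rows)
    fixed_df = case_results_frame(fixed_rows)

    # group t-tests on fixed-window scores
    group_rows = []
    for system in params.systems:
        for cname, spec in specs.items():
            highs = []
            for s in range(params.n_subjects):
                sid = f"S{s:02d}"
                sub = fixed_df[(fixed_df.subject_id == sid)
                               & (fixed_df.system == system)
                               & (fixed_df.component == cname)]
                if len(sub):
                    highs.append(float(sub.observed_difference.iloc[0]))
            if len(highs) >= 2 and np.std(highs, ddof=1) > 0:
                diffs = np.asarray(highs)
                t, df_, p, d = paired_t_cohens_d(diffs, np.zeros_like(diffs))
                group_rows.append({
                    "system": system, "component": cname,
                    "mean_diff": float(diffs.mean()),
                    "sd_diff": float(diffs.std(ddof=1)),
                    "t": t, "df": df_, "p": p, "cohens_d": d,
                    "n": len(diffs),
                })
    group_df = pd.DataFrame(group_rows)

    # Cochran-Q across p-criteria (cases = subject x system rows)
    cochran = {}
    for cname in specs:
        sub = case_df[case_df.component == cname]
        mat = np.column_stack([
            sub[f"sig_p{a:g}"].to_numpy(dtype=int) for a in criteria])
        try:
            cochran[cname] = cochran_q(mat)
        except ValueError as err:
            cochran[cname] = {"error": str(err)}

    # McNemar on first vs second halves at the loosest criterion
    mcnemar_res = {}
    halves_df = pd.DataFrame(halves_rows) if halves_rows else None
    if halves_df is not None and len(halves_df):
        a0 = criteria[0]
        for cname in specs:
            sub = halves_df[halves_df.component == cname]
            piv = sub.pivot_table(index=["subject_id", "system"],
                                  columns="half", values=f"sig_p{a0:g}",
                                  aggfunc="first")
            b = int(((piv["first"] == 1) & (piv["second"] == 0)).sum())
            c = int(((piv["first"] == 0) & (piv["second"] == 1)).sum())
            mcnemar_res[cname] = {"b": b, "c": c, "p": mcnemar_exact(b, c)}

    # EPN-LPP magnitude correlation per system (adaptive differences)
    correlations = {}
    for system in params.systems:
        epn = adaptive_diffs.get((system, "EPN"), {})
        lpp = adaptive_diffs.get((system, "LPP"), {})
        common = sorted(set(epn) & set(lpp))
        if len(common) >= 3:
            try:
                r, p = correlate_components([epn[k] for k in common],
                                            [lpp[k] for k in common])
                correlations[system] = {"r": r, "p": p, "n": len(common)}
            except ValueError as err:
                correlations[system] = {"error": str(err)}

    report = StudyReport(
        sensitivity_adaptive=sensitivity_table(case_df, criteria),
        sensitivity_fixed=sensitivity_table(fixed_df, criteria),
        false_alarms=false_alarm_table(spec_results, criteria)
        if spec_results else None,
        group_tests=group_df,
        cochran_criteria=cochran,
        mcnemar_halves=mcnemar_res,
        correlations=correlations,
        case_results=case_df,
        specificity_results=results_frame(spec_results) if spec_results else None,
        halves_results=halves_df,
        qc=pd.DataFrame(qc_rows),
    )
    if out_dir is not None:
        report.write(out_dir)
    return report
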