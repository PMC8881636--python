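#!/usr/bin/env python
"""Group-level statistics over the per-case results.

Paired t-tests (high vs low arousal) with Cohen's d on the fixed-window
scores per behavior system; Cochran-Q over the graded p-criteria on the
adaptive-window significance flags; and the per-system correlation between
each subject's EPN and LPP difference magnitudes.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from erpcase.group import cochran_q, correlate_components, paired_t_cohens_d

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
CRITERIA = (0.05, 0.025, 0.01, 0.001, 0.00002)


def main() -> None:
    adaptive = pd.read_csv(RESULTS / "case_results.csv")
    fixed = pd.read_csv(RESULTS / "case_results_fixed.csv")

    group_rows = []
    for (system, comp), grp in fixed.groupby(["system", "component"]):
        diffs = grp["observed_difference"].to_numpy()
        t, df_, p, d = paired_t_cohens_d(diffs, np.zeros_like(diffs))
        group_rows.append({
            "system": system, "component": comp,
            "mean_diff_uv": round(diffs.mean(), 2),
            "sd_uv": round(diffs.std(ddof=1), 2),
            "t": round(t, 2), "df": df_, "p": float(f"{p:.2g}"),
            "cohens_d": round(d, 2),
        })
    group_df = pd.DataFrame(group_rows)
    group_df.to_csv(RESULTS / "group_stats.csv", index=False)
    print("--- dependent t-tests on fixed-window scores (high - low) ---")
    print(group_df.to_string(index=False))

    summary = {"cochran_q_criteria": {}, "correlations": {}}
    for comp in ("EPN", "LPP"):
        sub = adaptive[adaptive.component == comp]
        mat = np.column_stack([sub[f"sig_p{a:g}"].to_numpy(dtype=int)
                               for a in CRITERIA])
        res = cochran_q(mat)
        summary["cochran_q_criteria"][comp] = {
            "Q": round(res["Q"], 1), "df": res["df"],
            "p": float(f"{res['p']:.2g}")}
        print(f"\n{comp}: Cochran-Q over the five p-criteria "
              f"Q({res['df']}) = {res['Q']:.1f}, p = {res['p']:.2g} "
              f"(decline of significant cases with stricter criteria)")

    for system, grp in adaptive.groupby("system"):
        piv = grp.pivot_table(index="subject_id", columns="component",
                              values="observed_difference")
        r, p = correlate_components(piv["EPN"], piv["LPP"])
        summary["correlations"][system] = {"r": round(r, 2),
                                           "p": round(p, 3)}
        print(f"EPN-LPP magnitude correlation, {system}: "
              f"r = {r:.2f} (p = {p:.2f}, n = {len(piv)})")

    (RESULTS / "group_stats.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
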