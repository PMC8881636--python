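#!/usr/bin/env python
"""Single-subject bootstrap tests of the EPN and LPP emotional modulation.

Loads every simulated case, preprocesses it (band filters, baseline,
average reference, artifact rejection, trial-count equating), scores both
components in individually adapted windows and in the fixed group windows,
and bootstrap-tests each difference (2000 replicates here).  Writes the
per-case results and the sensitivity tables across the five graded
p-criteria.
"""

from pathlib import Path

from erpcase.casestats import BootstrapConfig, child_seed, run_case_analysis
from erpcase.epochs import load_npz
from erpcase.group import case_results_frame, sensitivity_table
from erpcase.preprocess import preprocess
from erpcase.scoring import default_component_specs

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "study_data"
RESULTS = ROOT / "results"
SEED = 1
BOOT = BootstrapConfig(n_boot=2000, seed=SEED)


def main() -> None:
    paths = sorted(DATA_DIR.glob("*.npz"))
    if not paths:
        raise SystemExit("run 01_simulate_study.py first")
    results = {"adaptive": [], "fixed": []}
    for path in paths:
        raw = load_npz(path)
        ep = preprocess(raw, equate_seed=child_seed(
            SEED, raw.subject_id, raw.system, "equate"))
        specs = default_component_specs(ep.n_sensors)
        for mode in ("adaptive", "fixed"):
            results[mode].extend(run_case_analysis(ep, specs, BOOT,
                                                   mode=mode))
    for mode, rows in results.items():
        df = case_results_frame(rows)
        suffix = "" if mode == "adaptive" else "_fixed"
        df.to_csv(RESULTS / f"case_results{suffix}.csv", index=False)
        table = sensitivity_table(df, BOOT.criteria)
        table.to_csv(RESULTS / f"sensitivity_table{suffix}.csv", index=False)
        print(f"--- sensitivity, {mode} windows (% of 16 subjects) ---")
        print(table.to_string(index=False))


if __name__ == "__main__":
    main()
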