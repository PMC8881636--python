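#!/usr/bin/env python
"""Habituation control: first vs second half of the trials.

Repeated stimulus presentation could blunt the emotional modulation over
a session.  Each case's trials are split chronologically within condition,
both halves are bootstrap-tested separately, and the proportions of
significant cases are compared with an exact McNemar test on the
discordant cases.
"""

import json
from pathlib import Path

import pandas as pd

from erpcase.casestats import (BootstrapConfig, child_seed,
                               run_case_analysis, split_halves)
from erpcase.epochs import load_npz
from erpcase.group import mcnemar_exact
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
    rows = []
    for path in paths:
        raw = load_npz(path)
        ep = preprocess(raw, equate_seed=child_seed(
            SEED, raw.subject_id, raw.system, "equate"))
        specs = default_component_specs(ep.n_sensors)
        for half_name, half in zip(("first", "second"), split_halves(ep)):
            for res in run_case_analysis(half, specs, BOOT, mode="adaptive"):
                row = res.to_row()
                row["half"] = half_name
                rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "halves_results.csv", index=False)

    out = {}
    for comp in ("EPN", "LPP"):
        sub = df[df.component == comp]
        piv = sub.pivot_table(index=["subject_id", "system"], columns="half",
                              values="sig_p0.05", aggfunc="first")
        b = int(((piv["first"] == 1) & (piv["second"] == 0)).sum())
        c = int(((piv["first"] == 0) & (piv["second"] == 1)).sum())
        p = mcnemar_exact(b, c)
        out[comp] = {"first_half_pct": round(100 * piv["first"].mean()),
                     "second_half_pct": round(100 * piv["second"].mean()),
                     "b": b, "c": c, "mcnemar_p": round(p, 4)}
        print(f"{comp}: {out[comp]['first_half_pct']}% significant in the "
              f"first half vs {out[comp]['second_half_pct']}% in the second "
              f"(discordant {b}/{c}, exact McNemar p = {p:.3f})")
    (RESULTS / "habituation_mcnemar.json").write_text(
        json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
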