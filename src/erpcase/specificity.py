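"""Specificity (false-alarm) analysis on mirrored-picture null contrasts.

Left- and right-mirrored presentations of the same pictures should evoke
identical ERPs, so treating the mirror split as a pseudo-condition
contrast yields tests for which no effect is predicted.  For each picture
category (high/low arousal) and component, the left/right trials become
pseudo-high/pseudo-low, counts are equated, the component is scored with
the same parameters as the main analysis, and one-sided bootstrap tests
are run in both directions (left > right and right > left) — four times
as many tests per case as the main analysis.  The proportion of
significant tests is the false-alarm rate (100 - specificity).

With fixed windows the two directions share one bootstrap distribution
(the statistic only changes sign); in adaptive mode the window is selected
per direction (maximizing that direction's signed difference), so each
direction carries its own distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .casestats import (BootstrapConfig, bootstrap_distribution, bootstrap_p,
                        child_seed, classify_significance, per_trial_scores)
from .epochs import EpochSet
from .preprocess import equate_trials
from .scoring import score_component

DIRECTIONS = ("left_gt_right", "right_gt_left")


@dataclass
class SpecificityResult:
    subject_id: str
    system: str
    component: str
    picture_category: str  # "high" | "low"
    direction: str         # "left_gt_right" | "right_gt_left"
    observed_difference: float  # left - right in the scored window
    window_used: tuple
    p: float
    significance_flags: dict

    def to_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "system": self.system,
            "component": self.component,
            "picture_category": self.picture_category,
            "direction": self.direction,
            "observed_difference": self.observed_difference,
            "window_start_ms": self.window_used[0],
            "window_end_ms": self.window_used[1],
            "p": self.p,
        }
        for alpha, flag in self.significance_flags.items():
            row[f"sig_p{alpha:g}"] = bool(flag)
        return row


def mirror_split(epochs: EpochSet, category: str) -> tuple:
    """The category's trials partitioned by mirror label."""
    cat_mask = epochs.condition == category
    if not cat_mask.any():
        raise ValueError(f"category {category!r} not present")
    left = cat_mask & (epochs.mirror == "left")
    right = cat_mask & (epochs.mirror == "right")
    if not left.any() or not right.any():
        raise ValueError(f"category {category!r} lacks a mirror label")
    return (epochs.subset(np.flatnonzero(left), note=f"{category}/left"),
            epochs.subset(np.flatnonzero(right), note=f"{category}/right"))


def _pseudo_condition_set(epochs: EpochSet, category: str) -> EpochSet:
    """The category's trials with mirror labels recast as conditions
    (left -> high, right -> low), so the main-analysis machinery applies
    unchanged."""
    left, right = mirror_split(epochs, category)  # validates labels
    cat_idx = np.flatnonzero(epochs.condition == category)
    sub = epochs.subset(cat_idx, note=f"specificity {category}")
    pseudo = np.where(sub.mirror == "left", "high", "low").astype(object)
    return sub.with_conditions(pseudo, note="mirror as pseudo-condition")


def run_specificity(epochs: EpochSet, specs, config: BootstrapConfig,
                    mode: str = "adaptive") -> list:
    """All four null tests per component (2 categories x 2 directions)."""
    if isinstance(specs, dict):
        specs = list(specs.values())
    results = []
    for category in ("high", "low"):
        pseudo = _pseudo_condition_set(epochs, category)
        pseudo = equate_trials(
            pseudo, child_seed(config.seed, epochs.subject_id, epochs.system,
                               category, "equate"))
        for spec in specs:
            for dir_label, sign in zip(DIRECTIONS, (+1, -1)):
                # direction of the one-sided test: the component's expected
                # sign if left plays "high", the opposite for right > left
                test_dir = sign * spec.direction
                if mode == "adaptive":
                    # adapt the window to this direction's signed difference
                    dir_spec = spec if sign == +1 else \
                        type(spec)(name=spec.name, cluster=spec.cluster,
                                   fixed_window=spec.fixed_window,
                                   search_range=spec.search_range,
                                   span_ms=spec.span_ms,
                                   direction=-spec.direction)
                    score = score_component(pseudo, dir_spec, mode="adaptive")
                else:
                    score = score_component(pseudo, spec, mode="fixed")
                scores = per_trial_scores(pseudo, spec.cluster, score.window_used)
                high = scores[pseudo.condition == "high"]
                low = scores[pseudo.condition == "low"]
                if mode == "fixed":
                    # shared distribution for both directions (sign flip)
                    rng = np.random.default_rng(
                        child_seed(config.seed, epochs.subject_id,
                                   epochs.system, category, spec.name))
                else:
                    rng = np.random.default_rng(
                        child_seed(config.seed, epochs.subject_id,
                                   epochs.system, category, spec.name,
                                   dir_label))
                dist = bootstrap_distribution(high, low, config, rng)
                p, _ = bootstrap_p(score.difference, dist, test_dir, "one")
                results.append(SpecificityResult(
                    subject_id=epochs.subject_id,
                    system=epochs.system,
                    component=spec.name,
                    picture_category=category,
                    direction=dir_label,
                    observed_difference=score.difference,
                    window_used=score.window_used,
                    p=p,
                    significance_flags=classify_significance(p, config.criteria),
                ))
    return results


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def false_alarm_table(results, criteria) -> pd.DataFrame:
    """Percentage of significant null tests per system x component x
    criterion, rounded to the nearest integer percent."""
    from .group import round_percent  # shared rounding convention

    if not results:
        raise ValueError("no specificity results")
    df = results_frame(results)
    rows = []
    for (system, component), grp in df.groupby(["system", "component"], sort=False):
        row = {"system": system, "component": component}
        for alpha in criteria:
            col = f"sig_p{alpha:g}"
            row[f"p<{alpha:g}"] = round_percent(int(grp[col].sum()), len(grp))
        rows.append(row)
    return pd.DataFrame(rows)
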