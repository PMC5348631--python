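"""Attentional-control (singleton) scoring and interview detail profiles.

The singleton score is a difference of differences on visual-search
reaction times: the RT cost of a color-singleton distractor in the
flexible-attention condition (where the singleton is sometimes the target
and cannot be filtered out wholesale) minus the same cost in the strategic
condition (where color is always irrelevant).  Higher scores mean poorer
flexible attentional control.

Interview scoring summarizes Autobiographical-Interview-style detail
tallies (internal episodic categories vs. external content) and quantifies
inter-rater agreement with Cronbach's alpha over paired rater totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple

import numpy as np
import pandas as pd

from .simulate import ALL_CATEGORIES, INTERNAL_CATEGORIES

__all__ = [
    "ExclusionReport",
    "filter_singleton_trials",
    "distraction_cost",
    "singleton_score",
    "tally_details",
    "cronbach_alpha",
]

#: Responses slower than this (ms) fall outside the response window.
RT_WINDOW_MS = 3000.0


@dataclass(frozen=True)
class ExclusionReport:
    """Accounting of visual-search trials removed before RT averaging."""

    n_total: int
    n_error: int
    n_missing: int
    n_too_slow: int

    @property
    def n_excluded(self) -> int:
        return self.n_error + self.n_missing + self.n_too_slow

    @property
    def percent_excluded(self) -> float:
        return 100.0 * self.n_excluded / self.n_total if self.n_total else 0.0


def filter_singleton_trials(
    records: pd.DataFrame,
) -> Tuple[pd.DataFrame, ExclusionReport]:
    """Drop error, missing and out-of-window responses.

    Returns the valid trials plus an :class:`ExclusionReport` with the
    pooled exclusion percentage across both conditions.
    """
    rt = records["rt_ms"]
    missing = rt.isna()
    too_slow = rt.gt(RT_WINDOW_MS) & ~missing
    error = ~records["correct"].astype(bool) & ~missing & ~too_slow
    keep = ~(missing | too_slow | error)
    report = ExclusionReport(
        n_total=len(records),
        n_error=int(error.sum()),
        n_missing=int(missing.sum()),
        n_too_slow=int(too_slow.sum()),
    )
    return records[keep].copy(), report


def distraction_cost(
    records: pd.DataFrame,
    condition: int,
    *,
    stat: Literal["mean", "median"] = "mean",
) -> float:
    """RT increase due to the colored distractor in one condition (ms).

    Mean RT on distractor-present minus distractor-absent trials, over
    valid trials of ``condition``.  Singleton-*target* trials (flexible
    condition only) are a different event type — there is no colored
    distractor on them — and are excluded from both cells.
    """
    sub = records[
        (records["condition"] == condition)
        & ~records["singleton_target"].astype(bool)
    ]
    agg = np.mean if stat == "mean" else np.median
    cells = {}
    for present in (True, False):
        cell = sub.loc[sub["distractor_present"].astype(bool) == present, "rt_ms"]
        if len(cell) == 0:
            label = "present" if present else "absent"
            raise ValueError(
                f"no valid distractor-{label} trials in condition {condition}"
            )
        cells[present] = float(agg(cell.to_numpy(dtype=float)))
    return cells[True] - cells[False]


def singleton_score(
    records: pd.DataFrame,
    *,
    stat: Literal["mean", "median"] = "mean",
    flexible_condition: int = 2,
    strategic_condition: int = 1,
) -> float:
    """Flexible-minus-strategic distractor cost (ms); higher = poorer control."""
    return distraction_cost(records, flexible_condition, stat=stat) - \
        distraction_cost(records, strategic_condition, stat=stat)


def tally_details(rows: pd.DataFrame) -> pd.DataFrame:
    """Summarize interview detail tallies per familiarity level.

    Input rows follow the interview schema (subject_id, event_id,
    familiarity, rater, category, count).  Output has one row per
    (familiarity, measure) with the mean and SD over events of the
    per-event count, where measures are each internal sub-category plus
    the ``internal`` total (sum of the five sub-categories) and
    ``external``.  Counts are averaged over raters within an event first.
    """
    unknown = set(rows["category"]) - set(ALL_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown detail categories: {sorted(unknown)}")
    # mean over raters within each (subject, event, category) cell
    per_event = (
        rows.groupby(["subject_id", "event_id", "familiarity", "category"],
                     observed=True)["count"]
        .mean()
        .unstack("category")
        .reindex(columns=list(ALL_CATEGORIES), fill_value=0)
        .fillna(0.0)
    )
    per_event["internal"] = per_event[list(INTERNAL_CATEGORIES)].sum(axis=1)
    measures = ["internal", *INTERNAL_CATEGORIES, "external"]
    out = []
    for familiarity, group in per_event.groupby(level="familiarity"):
        for measure in measures:
            vals = group[measure].to_numpy(dtype=float)
            out.append({
                "familiarity": familiarity,
                "measure": measure,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n_events": len(vals),
            })
    return pd.DataFrame(out)


def cronbach_alpha(rater1, rater2) -> float:
    """Cronbach's alpha for two raters scoring the same items.

    ``alpha = (m / (m - 1)) * (1 - sum(var_i) / var_total)`` with m = 2
    raters, item variances and the variance of the rater-sum computed over
    items (ddof = 1).  Equals 1 exactly when the raters differ by a
    constant; can be negative under disagreement.
    """
    r1 = np.asarray(rater1, dtype=float)
    r2 = np.asarray(rater2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rater score vectors must be 1-D and equal length")
    if len(r1) < 2:
        raise ValueError("need at least two items")
    total_var = np.var(r1 + r2, ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance: alpha is undefined")
    item_var = np.var(r1, ddof=1) + np.var(r2, ddof=1)
    return float(2.0 * (1.0 - item_var / total_var))
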