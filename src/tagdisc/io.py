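"""CSV/JSON readers and writers for all pipeline stages.

All tables are UTF-8 CSV with a header row and "." as the decimal
separator.  Writers and readers are exact round-trips for the schemas
below; schedules carry a JSON sidecar manifest recording the construction
parameters (pretest k, seed, ladder offsets) so a schedule file is fully
reproducible from its manifest.

Schemas
-------
choices:    subject_id, condition, delay_days, amount_eur, choice, rt_ms
schedule:   block_index, trial_index, condition, partner_slot, delay_days, amount_eur
attention:  subject_id, condition, distractor_present, singleton_target, rt_ms, correct
interview:  subject_id, event_id, familiarity, rater, category, count
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from .simulate import CohortSpec
from .types import CONDITIONS, TAG, TrialSchedule

__all__ = [
    "RunConfig", "load_config",
    "read_choices", "write_choices",
    "read_schedule", "write_schedule",
    "read_attention", "write_attention",
    "read_interview", "write_interview",
]

PathLike = Union[str, Path]

CHOICE_COLUMNS = ["subject_id", "condition", "delay_days", "amount_eur", "choice", "rt_ms"]
SCHEDULE_COLUMNS = ["block_index", "trial_index", "condition", "partner_slot",
                    "delay_days", "amount_eur"]
ATTENTION_COLUMNS = ["subject_id", "condition", "distractor_present",
                     "singleton_target", "rt_ms", "correct"]
INTERVIEW_COLUMNS = ["subject_id", "event_id", "familiarity", "rater", "category", "count"]


class RunConfig(BaseModel):
    """Validated configuration for the command-line pipeline."""

    out_dir: str = "tagdisc_out"
    seed: int = 0
    pretest_k: float = Field(default=0.085, ge=0)
    cohort: CohortSpec = Field(default_factory=CohortSpec)


def load_config(path: PathLike) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        if path.suffix.lower() == ".json":
            raw = json.load(fh)
        else:
            raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)


def _check_columns(frame: pd.DataFrame, expected: list, what: str) -> None:
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} table is missing columns {missing}")


def write_choices(frame: pd.DataFrame, path: PathLike) -> None:
    _check_columns(frame, CHOICE_COLUMNS, "choice")
    frame[CHOICE_COLUMNS].to_csv(path, index=False)


def read_choices(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, CHOICE_COLUMNS, "choice")
    bad = set(frame["condition"]) - set(CONDITIONS) - {TAG}
    if bad:
        raise ValueError(f"unknown conditions in choice table: {sorted(bad)}")
    bad = set(frame["choice"]) - {"delayed", "immediate"}
    if bad:
        raise ValueError(f"unknown choice labels: {sorted(bad)}")
    return frame


def write_schedule(schedule: TrialSchedule, path: PathLike) -> None:
    """Write the trial table plus a ``<path>.manifest.json`` sidecar."""
    path = Path(path)
    schedule.trials[SCHEDULE_COLUMNS].to_csv(path, index=False)
    manifest = {
        "k": schedule.k,
        "seed": schedule.seed,
        "ladder_offsets": list(schedule.ladder_offsets),
        "condition_order": list(schedule.condition_order),
    }
    with open(path.with_suffix(path.suffix + ".manifest.json"), "w",
              encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)


def read_schedule(path: PathLike) -> TrialSchedule:
    path = Path(path)
    trials = pd.read_csv(path)
    _check_columns(trials, SCHEDULE_COLUMNS, "schedule")
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    return TrialSchedule(
        trials=trials,
        condition_order=tuple(manifest["condition_order"]),
        k=float(manifest["k"]),
        seed=int(manifest["seed"]),
        ladder_offsets=tuple(manifest["ladder_offsets"]),
    )


def write_attention(frame: pd.DataFrame, path: PathLike) -> None:
    _check_columns(frame, ATTENTION_COLUMNS, "attention")
    frame[ATTENTION_COLUMNS].to_csv(path, index=False)


def read_attention(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, ATTENTION_COLUMNS, "attention")
    frame["distractor_present"] = frame["distractor_present"].astype(bool)
    frame["singleton_target"] = frame["singleton_target"].astype(bool)
    frame["correct"] = frame["correct"].astype(bool)
    return frame


def write_interview(frame: pd.DataFrame, path: PathLike) -> None:
    _check_columns(frame, INTERVIEW_COLUMNS, "interview")
    frame[INTERVIEW_COLUMNS].to_csv(path, index=False)


def read_interview(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path)
    _check_columns(frame, INTERVIEW_COLUMNS, "interview")
    return frame
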