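"""Core domain types for the episodic-tag discounting analysis.

Money is in euros, delays in integer days, reaction times in milliseconds
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import pandas as pd

#: The three experimental conditions of the discounting task.
CONDITIONS: Tuple[str, str, str] = ("control", "familiar", "unfamiliar")

#: Pooled label used when the two episodic conditions are fit jointly.
TAG = "tag"

#: Conditions that carry an episodic tag (imagined meeting in a café).
TAG_CONDITIONS: Tuple[str, str] = ("familiar", "unfamiliar")

#: The six delay pairs of the discounting task; on each trial one member of
#: the pair is drawn at random (delays in days).
DEFAULT_DELAY_PAIRS: Tuple[Tuple[int, int], ...] = (
    (1, 2), (6, 7), (13, 15), (28, 32), (85, 95), (170, 190),
)

#: Delayed amounts are restricted to this range (euros).
AMOUNT_BOUNDS: Tuple[float, float] = (20.5, 79.5)

#: Amounts are displayed in half-euro steps.
AMOUNT_STEP: float = 0.5


@dataclass(frozen=True)
class DelayedOption:
    """A delayed reward: ``amount`` euros available after ``delay`` days."""

    amount: float
    delay: int

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"amount must be positive, got {self.amount}")
        if self.delay < 0:
            raise ValueError(f"delay must be non-negative, got {self.delay}")


@dataclass(frozen=True)
class ImmediateReference:
    """The fixed immediate reward (20 € by default, never shown on screen)."""

    amount: float = 20.0

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError(f"amount must be positive, got {self.amount}")


@dataclass(frozen=True)
class ChoiceTrial:
    """One intertemporal decision.

    ``choice`` is ``"delayed"`` or ``"immediate"``; ``rt`` is the response
    time in milliseconds (``None`` when missing).
    """

    option: DelayedOption
    condition: str
    choice: str
    rt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS and self.condition != TAG:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.choice not in ("delayed", "immediate"):
            raise ValueError(f"unknown choice {self.choice!r}")
        if self.rt is not None and self.rt <= 0:
            raise ValueError(f"rt must be positive when present, got {self.rt}")


@dataclass
class DiscountParams:
    """Fitted softmax-hyperbolic parameters for one subject × condition.

    ``k`` is the hyperbolic discount rate per day (higher = steeper
    discounting, i.e. more impatient); ``beta`` is the decision-noise
    temperature of the softmax rule (higher = noisier choices).  ``nll`` is
    the negative log-likelihood at the optimum, ``n_clipped`` counts choice
    probabilities that had to be clipped away from 0/1 before the log.
    """

    k: float
    beta: float
    nll: float
    n_trials: int
    converged: bool
    n_clipped: int = 0


@dataclass
class TrialSchedule:
    """A constructed 6-block × 36-trial session for one subject.

    ``trials`` has columns ``block_index, trial_index, condition,
    partner_slot, delay_days, amount_eur``.  ``condition_order`` lists the
    three conditions in presentation order (each condition occupies two
    adjacent blocks).
    """

    trials: pd.DataFrame
    condition_order: Tuple[str, str, str]
    k: float
    seed: int
    ladder_offsets: Tuple[float, ...] = (0.10, 0.25, 0.45)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def block(self, index: int) -> pd.DataFrame:
        return self.trials[self.trials["block_index"] == index]


@dataclass
class CohortDataset:
    """Everything the analysis stages consume for one simulated cohort.

    ``truths`` has one row per subject with the generative parameters
    (per-condition k and sqrt-k, beta, tag-effect, singleton-score truth,
    memory score, gender).  The trial-level tables follow the CSV schemas of
    the io module and may be ``None`` when only truths were generated.
    """

    truths: pd.DataFrame
    choices: Optional[pd.DataFrame] = None
    attention: Optional[pd.DataFrame] = None
    interview: Optional[pd.DataFrame] = None
    schedules: dict = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def n_subjects(self) -> int:
        return len(self.truths)


def trials_from_frame(frame: pd.DataFrame) -> list[ChoiceTrial]:
    """Convert a choice table (io schema) into ``ChoiceTrial`` objects."""
    out = []
    for row in frame.itertuples(index=False):
        rt = getattr(row, "rt_ms", None)
        out.append(
            ChoiceTrial(
                option=DelayedOption(float(row.amount_eur), int(row.delay_days)),
                condition=str(row.condition),
                choice=str(row.choice),
                rt=None if rt is None or pd.isna(rt) else float(rt),
            )
        )
    return out
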