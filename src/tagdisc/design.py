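"""Adaptive, participant-specific trial schedules for the discounting task.

A pretest discount rate ``k`` determines, for each delay, the indifference
amount (the delayed amount the participant values exactly as much as the
fixed 20 € immediate reward).  Each delay is then paired with six amounts
placed symmetrically above and below that indifference point, so that a
chooser with the same ``k`` is pulled toward choosing the delayed option on
about half of the trials.  Amounts are kept inside [20.5, 79.5] € in
half-euro steps, which caps the ladder when the indifference point falls
near or beyond the admissible range (long delays combined with steep
discounting).

A session is six 36-trial blocks, two adjacent blocks per condition, with
the condition order randomized across participants.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import indifference_amount
from .types import (
    AMOUNT_BOUNDS,
    AMOUNT_STEP,
    CONDITIONS,
    DEFAULT_DELAY_PAIRS,
    ImmediateReference,
    TrialSchedule,
    TAG_CONDITIONS,
)

__all__ = ["build_amount_ladder", "build_block", "build_session"]

#: Symmetric ladder offsets as fractions of the indifference amount.
DEFAULT_LADDER_OFFSETS: Tuple[float, float, float] = (0.10, 0.25, 0.45)


def _round_step(x: np.ndarray, step: float = AMOUNT_STEP) -> np.ndarray:
    return np.round(np.asarray(x, dtype=float) / step) * step


def _resolve_duplicates(
    amounts: np.ndarray,
    lo: float,
    hi: float,
    step: float = AMOUNT_STEP,
) -> np.ndarray:
    """Make the sorted rung list strictly increasing within [lo, hi].

    Collisions produced by clamping/rounding are nudged apart in ``step``
    increments: first an upward sweep from the low end, then a downward
    sweep from the high end so nothing is pushed past the cap.  The amount
    range holds far more than six half-euro slots, so this always succeeds.
    """
    v = np.sort(amounts.astype(float))
    for i in range(1, len(v)):
        if v[i] <= v[i - 1] + step / 2:
            v[i] = v[i - 1] + step
    if v[-1] > hi:
        v[-1] = hi
        for i in range(len(v) - 2, -1, -1):
            if v[i] >= v[i + 1] - step / 2:
                v[i] = v[i + 1] - step
    return v


def build_amount_ladder(
    k: float,
    delay: int,
    ref: ImmediateReference = ImmediateReference(),
    *,
    offsets: Sequence[float] = DEFAULT_LADDER_OFFSETS,
    bounds: Tuple[float, float] = AMOUNT_BOUNDS,
    clamp: bool = True,
) -> np.ndarray:
    """Six delayed amounts bracketing the indifference point for one delay.

    Three rungs below and three above the indifference amount, at symmetric
    fractional offsets, rounded to half euros and (by default) clamped into
    ``bounds`` with duplicate rungs nudged apart.  ``clamp=False`` returns
    the raw symmetric rungs, useful for checking the symmetry of the
    construction itself.
    """
    center = indifference_amount(k, delay, ref)
    offs = np.asarray(offsets, dtype=float)
    raw = np.concatenate([center * (1.0 - offs), center * (1.0 + offs)])
    raw = np.sort(raw)
    if not clamp:
        return raw
    lo, hi = bounds
    rungs = _round_step(np.clip(raw, lo, hi))
    return _resolve_duplicates(rungs, lo, hi)


def build_block(
    k: float,
    condition: str,
    *,
    delay_pairs: Sequence[Tuple[int, int]] = DEFAULT_DELAY_PAIRS,
    rng: Union[int, np.random.Generator, None] = None,
    ref: ImmediateReference = ImmediateReference(),
    offsets: Sequence[float] = DEFAULT_LADDER_OFFSETS,
) -> pd.DataFrame:
    """One 36-trial block: six delay pairs crossed with six ladder rungs.

    For every (delay pair, rung index) cell one member of the pair is drawn
    uniformly and paired with that rung of the ladder computed at the drawn
    delay; the 36 trials are then shuffled.  Episodic conditions alternate
    deterministically between the two social partners (``partner_slot``
    1/2); the control condition uses slot 0 (placeholder strings).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(rng)
    rows = []
    for pair in delay_pairs:
        if not len(pair) == 2 or not pair[0] < pair[1]:
            raise ValueError(f"delay pair must be strictly increasing, got {pair}")
        for rung_idx in range(6):
            d = int(pair[rng.integers(2)])
            ladder = build_amount_ladder(k, d, ref, offsets=offsets)
            rows.append({"delay_days": d, "amount_eur": float(ladder[rung_idx])})
    frame = pd.DataFrame(rows)
    frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    frame.insert(0, "condition", condition)
    if condition in TAG_CONDITIONS:
        frame["partner_slot"] = np.arange(len(frame)) % 2 + 1
    else:
        frame["partner_slot"] = 0
    return frame


def build_session(
    k: float,
    seed: int,
    *,
    delay_pairs: Sequence[Tuple[int, int]] = DEFAULT_DELAY_PAIRS,
    ref: ImmediateReference = ImmediateReference(),
    offsets: Sequence[float] = DEFAULT_LADDER_OFFSETS,
) -> TrialSchedule:
    """A full six-block, 216-trial session for one participant.

    The order of the three conditions is a random permutation, but the two
    blocks of each condition are always adjacent (block-condition sequence
    AABBCC for some permutation A, B, C).
    """
    if k < 0:
        raise ValueError(f"pretest discount rate must be non-negative, got {k}")
    rng = np.random.default_rng(seed)
    order = tuple(np.array(CONDITIONS)[rng.permutation(3)])
    blocks = []
    block_index = 0
    for condition in order:
        for _ in range(2):
            block = build_block(
                k, condition, delay_pairs=delay_pairs, rng=rng,
                ref=ref, offsets=offsets,
            )
            block.insert(0, "trial_index", np.arange(len(block)))
            block.insert(0, "block_index", block_index)
            blocks.append(block)
            block_index += 1
    trials = pd.concat(blocks, ignore_index=True)
    trials = trials[
        ["block_index", "trial_index", "condition", "partner_slot",
         "delay_days", "amount_eur"]
    ]
    return TrialSchedule(
        trials=trials,
        condition_order=order,
        k=float(k),
        seed=int(seed),
        ladder_offsets=tuple(offsets),
    )
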