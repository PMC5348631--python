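"""Synthetic cohorts with the covariance structure the analysis assumes.

No behavioral data were deposited with the study this package models, so
every downstream stage is exercised on simulated cohorts instead.  The
generator draws, per subject, a control-condition discount rate (on the
square-root scale, where the distribution is roughly symmetric), an episodic
"tag-effect" (the change in sqrt-k when delays carry an imagined future
event), and a singleton attentional-control score, with the tag-effect and
singleton score drawn jointly at a configurable correlation ``rho`` — the
structure behind the finding that poorer attentional control goes with a
smaller benefit from episodic tags.  Choice, visual-search and interview
tables are then generated from these per-subject truths.

Distributional families (Normal sqrt-k, lognormal beta and RT, Gaussian
trial noise, Poisson detail tallies) are modelling conveniences; defaults
are centred on the summary statistics the study reports, not on deposited
raw data.
"""

from __future__ import annotations

import math
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from . import model as _model
from .design import build_session
from .types import (
    CONDITIONS,
    CohortDataset,
    ImmediateReference,
    TAG_CONDITIONS,
    TrialSchedule,
)

__all__ = [
    "CohortSpec",
    "simulate_choices",
    "simulate_singleton_trials",
    "simulate_interview",
    "simulate_truths",
    "simulate_cohort",
]

#: Interview detail categories (internal sub-categories plus external).
INTERNAL_CATEGORIES = ("time", "place", "perceptual", "emotion_thought", "event")
ALL_CATEGORIES = INTERNAL_CATEGORIES + ("external",)

# Mean detail counts per imagined event.  The four non-zero internal
# sub-category means sum to the internal total for each familiarity level;
# time details are effectively absent at these rates.
_FAMILIAR_RATES = {
    "time": 0.0, "place": 1.32, "perceptual": 1.55,
    "emotion_thought": 1.45, "event": 2.23, "external": 0.86,
}
_UNFAMILIAR_RATES = {
    "time": 0.0, "place": 1.14, "perceptual": 0.82,
    "emotion_thought": 1.82, "event": 2.09, "external": 0.68,
}

RngLike = Union[int, np.random.Generator, None]


class CohortSpec(BaseModel):
    """Generative parameters for one synthetic cohort.

    Defaults emulate the older-adult cohort: n = 22 with 9 men, a control
    discount-rate median near 0.085/day (sqrt-k ~ 0.29), an essentially
    null mean tag-effect, and a singleton score of 71.3 +/- 89.3 ms whose
    correlation with the tag-effect is ``rho_singleton_tag``.
    """

    model_config = ConfigDict(validate_assignment=True)

    n_subjects: int = Field(default=22, ge=2)

    # Discounting truths (sqrt-k scale, per day**0.5)
    sqrt_k_mean: float = Field(default=0.29, ge=0)
    sqrt_k_sd: float = Field(default=0.15, gt=0)
    tag_effect_mean: float = -0.005
    tag_effect_sd: float = Field(default=0.08, ge=0)
    condition_noise_sd: float = Field(default=0.03, ge=0)
    rho_singleton_tag: float = Field(default=-0.67, ge=-1.0, le=1.0)

    # Softmax temperature (euros), lognormal across subjects
    beta_median: float = Field(default=2.5, gt=0)
    beta_log_sd: float = Field(default=0.6, ge=0)

    # Demographics / covariates
    p_male: float = Field(default=9 / 22, ge=0, le=1)
    memory_mean: float = 47.5
    memory_sd: float = Field(default=10.34, gt=0)

    # Visual-search task
    singleton_mean: float = 71.34
    singleton_sd: float = Field(default=89.29, gt=0)
    base_rt_ms: float = Field(default=850.0, gt=0)
    distractor_cost_cond1_ms: float = 30.0
    rt_noise_sd_ms: float = Field(default=150.0, ge=0)
    error_rate: float = Field(default=0.03, ge=0, le=1)
    miss_rate: float = Field(default=0.015, ge=0, le=1)
    singleton_target_rate: float = Field(default=0.08, ge=0, le=1)
    n_blocks_per_condition: int = Field(default=4, ge=1)
    n_trials_per_block: int = Field(default=48, ge=2)

    # Interview generator
    familiar_rates: Dict[str, float] = Field(default_factory=lambda: dict(_FAMILIAR_RATES))
    unfamiliar_rates: Dict[str, float] = Field(default_factory=lambda: dict(_UNFAMILIAR_RATES))
    rater_disagreement_prob: float = Field(default=0.25, ge=0, le=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check_rates(self) -> "CohortSpec":
        for rates in (self.familiar_rates, self.unfamiliar_rates):
            unknown = set(rates) - set(ALL_CATEGORIES)
            if unknown:
                raise ValueError(f"unknown interview categories: {sorted(unknown)}")
            if any(v < 0 for v in rates.values()):
                raise ValueError("interview rates must be non-negative")
        return self


def _as_rng(rng: RngLike) -> np.random.Generator:
    return rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)


def simulate_choices(
    schedule: TrialSchedule,
    k_true: Union[float, Dict[str, float]],
    beta_true: float,
    rng: RngLike = None,
    *,
    ref: ImmediateReference = ImmediateReference(),
    rt_log_mean: float = math.log(880.0),
    rt_log_sd: float = 0.35,
) -> pd.DataFrame:
    """Bernoulli choices for every planned trial of a schedule.

    ``k_true`` may be a scalar (one rate for all conditions) or a mapping
    ``condition -> k``.  Choice probabilities come from the same
    hyperbolic + softmax model the fitting stage assumes; response times
    are lognormal window dressing, not part of the model.
    """
    if beta_true <= 0:
        raise ValueError(f"beta must be positive, got {beta_true}")
    rng = _as_rng(rng)
    trials = schedule.trials
    if isinstance(k_true, dict):
        k = trials["condition"].map(k_true).to_numpy(dtype=float)
        if np.any(np.isnan(k)):
            missing = sorted(set(trials["condition"]) - set(k_true))
            raise ValueError(f"k_true missing conditions {missing}")
    else:
        k = float(k_true)
    sv = trials["amount_eur"].to_numpy() / (1.0 + k * trials["delay_days"].to_numpy())
    p_delayed = expit((sv - ref.amount) / beta_true)
    chose_delayed = rng.random(len(trials)) < p_delayed
    rt = np.exp(rng.normal(rt_log_mean, rt_log_sd, size=len(trials)))
    out = trials.copy()
    out["choice"] = np.where(chose_delayed, "delayed", "immediate")
    out["rt_ms"] = np.round(rt, 1)
    return out


def simulate_singleton_trials(
    ability: float,
    spec: CohortSpec,
    rng: RngLike = None,
    *,
    subject_id: Union[int, str] = 0,
) -> pd.DataFrame:
    """Visual-search trials for one subject in both task conditions.

    Condition 1 (strategic attention: color can be ignored throughout)
    carries a small, ability-independent distractor cost; condition 2
    (flexible attention: the color singleton is sometimes the target)
    carries that same cost plus the subject's ``ability`` term, so a
    noiseless simulation returns ``ability`` as its singleton score
    exactly.  Distractors appear on half the trials; in condition 2 the
    singleton is the target on ``singleton_target_rate`` of trials.
    Errors and omitted responses occur at the spec rates.
    """
    rng = _as_rng(rng)
    cost = {1: spec.distractor_cost_cond1_ms,
            2: spec.distractor_cost_cond1_ms + ability}
    frames = []
    n = spec.n_trials_per_block
    for condition in (1, 2):
        for _ in range(spec.n_blocks_per_condition):
            distractor = np.zeros(n, dtype=bool)
            distractor[rng.permutation(n)[: n // 2]] = True
            if condition == 2:
                singleton_target = rng.random(n) < spec.singleton_target_rate
                # a singleton target replaces the colored distractor
                distractor &= ~singleton_target
            else:
                singleton_target = np.zeros(n, dtype=bool)
            rt = (
                spec.base_rt_ms
                + cost[condition] * distractor
                + rng.normal(0.0, spec.rt_noise_sd_ms, size=n)
            )
            rt = np.minimum(rt, 3000.0)
            correct = rng.random(n) >= spec.error_rate
            missing = rng.random(n) < spec.miss_rate
            rt = np.where(missing, np.nan, rt)
            frames.append(pd.DataFrame({
                "subject_id": subject_id,
                "condition": condition,
                "distractor_present": distractor,
                "singleton_target": singleton_target,
                "rt_ms": rt,
                "correct": correct,
            }))
    return pd.concat(frames, ignore_index=True)


def simulate_interview(
    spec: CohortSpec,
    rng: RngLike = None,
    *,
    subject_id: Union[int, str] = 0,
) -> pd.DataFrame:
    """Paired-rater detail tallies for one subject's four imagined events.

    Rater 1 draws Poisson counts per category at the familiarity-specific
    rates; rater 2 re-codes rater 1's counts with a symmetric +/-1
    perturbation applied independently per cell with probability
    ``rater_disagreement_prob`` (clipped at zero), which controls
    inter-rater agreement.
    """
    rng = _as_rng(rng)
    rows = []
    events = [(1, "familiar"), (2, "familiar"), (3, "unfamiliar"), (4, "unfamiliar")]
    for event_id, familiarity in events:
        rates = spec.familiar_rates if familiarity == "familiar" else spec.unfamiliar_rates
        for category in ALL_CATEGORIES:
            c1 = int(rng.poisson(rates.get(category, 0.0)))
            c2 = c1
            if rng.random() < spec.rater_disagreement_prob:
                c2 = max(0, c1 + (1 if rng.random() < 0.5 else -1))
            for rater, count in ((1, c1), (2, c2)):
                rows.append({
                    "subject_id": subject_id, "event_id": event_id,
                    "familiarity": familiarity, "rater": rater,
                    "category": category, "count": count,
                })
    return pd.DataFrame(rows)


def simulate_truths(spec: CohortSpec, rng: RngLike = None) -> pd.DataFrame:
    """Per-subject generative parameters for a cohort.

    The tag-effect ``delta`` (change in sqrt-k under episodic tags) and the
    singleton score are drawn jointly with correlation
    ``rho_singleton_tag``; each condition's sqrt-k truth additionally gets
    independent session-level noise (``condition_noise_sd``), so under a
    null tag-effect the three conditions are exchangeable.
    """
    rng = _as_rng(rng)
    n = spec.n_subjects
    lo = math.sqrt(_model.K_BOUNDS[0])
    hi = math.sqrt(_model.K_BOUNDS[1])

    s = rng.normal(spec.sqrt_k_mean, spec.sqrt_k_sd, size=n)
    z_delta = rng.standard_normal(n)
    z_single = rng.standard_normal(n)
    delta = spec.tag_effect_mean + spec.tag_effect_sd * z_delta
    rho = spec.rho_singleton_tag
    if spec.tag_effect_sd > 0:
        shared = rho * z_delta + math.sqrt(1.0 - rho**2) * z_single
    else:
        shared = z_single
    singleton = spec.singleton_mean + spec.singleton_sd * shared

    eps = rng.normal(0.0, spec.condition_noise_sd, size=(n, 3))
    sqrt_k = {
        "control": np.clip(s + eps[:, 0], lo, hi),
        "familiar": np.clip(s + delta + eps[:, 1], lo, hi),
        "unfamiliar": np.clip(s + delta + eps[:, 2], lo, hi),
    }
    beta = np.exp(rng.normal(math.log(spec.beta_median), spec.beta_log_sd, size=n))
    beta = np.clip(beta, *_model.BETA_BOUNDS)

    truths = pd.DataFrame({
        "subject_id": np.arange(n),
        "sqrt_k_control_true": sqrt_k["control"],
        "sqrt_k_familiar_true": sqrt_k["familiar"],
        "sqrt_k_unfamiliar_true": sqrt_k["unfamiliar"],
        "tag_effect_true": delta,
        "beta_true": beta,
        "singleton_true": singleton,
        "memory_score": np.round(
            np.clip(rng.normal(spec.memory_mean, spec.memory_sd, size=n), 0, 75), 1
        ),
        "gender": np.where(rng.random(n) < spec.p_male, "m", "f"),
    })
    for cond in CONDITIONS:
        truths[f"k_{cond}_true"] = truths[f"sqrt_k_{cond}_true"] ** 2
    return truths


def simulate_cohort(
    spec: CohortSpec,
    *,
    include_trials: bool = True,
) -> CohortDataset:
    """A complete synthetic cohort driven by ``spec.seed``.

    Draws per-subject truths, then (unless ``include_trials=False``)
    builds each subject's adaptive schedule from their control-condition
    discount rate — standing in for the pretest estimate — and simulates
    choice, visual-search and interview tables from the truths.
    """
    root = np.random.default_rng(spec.seed)
    truths = simulate_truths(spec, root)
    if not include_trials:
        return CohortDataset(truths=truths, seed=spec.seed)

    choice_frames, attention_frames, interview_frames = [], [], []
    schedules = {}
    # independent child seeds per subject, derived from the master seed
    seeds = root.integers(0, 2**31 - 1, size=(spec.n_subjects, 3))
    for i, row in truths.iterrows():
        sid = int(row["subject_id"])
        schedule = build_session(float(row["k_control_true"]), int(seeds[i, 0]))
        schedules[sid] = schedule
        k_map = {c: float(row[f"k_{c}_true"]) for c in CONDITIONS}
        choices = simulate_choices(
            schedule, k_map, float(row["beta_true"]), int(seeds[i, 1])
        )
        choices.insert(0, "subject_id", sid)
        choice_frames.append(choices)
        child = np.random.default_rng(seeds[i, 2])
        attention_frames.append(
            simulate_singleton_trials(float(row["singleton_true"]), spec, child,
                                      subject_id=sid)
        )
        interview_frames.append(simulate_interview(spec, child, subject_id=sid))
    return CohortDataset(
        truths=truths,
        choices=pd.concat(choice_frames, ignore_index=True),
        attention=pd.concat(attention_frames, ignore_index=True),
        interview=pd.concat(interview_frames, ignore_index=True),
        schedules=schedules,
        seed=spec.seed,
    )
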