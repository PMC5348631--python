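"""Hyperbolic discounting with softmax choice: likelihood and MLE fitting.

The model values a delayed reward of ``A`` euros at ``D`` days as the Mazur
hyperbola ``SV = A / (1 + k D)`` and chooses the delayed option with
probability ``P = logistic((SV - A_immediate) / beta)``.

``beta`` follows the *temperature* convention: larger ``beta`` means noisier,
more random choices.  Some toolboxes use the inverse-temperature convention
``P = logistic(beta * dSV)``; an inverse-temperature value converts to this
parameterization as ``beta_temperature = 1 / beta_inverse``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .types import ChoiceTrial, DelayedOption, DiscountParams, ImmediateReference

__all__ = [
    "K_BOUNDS",
    "BETA_BOUNDS",
    "subjective_value",
    "choice_probability",
    "negative_log_likelihood",
    "fit_mle",
    "transform_k",
    "indifference_amount",
]

#: Fitting bounds for the discount rate (per day).  Generous around the
#: plausible range (group medians sit near 0.08/day).
K_BOUNDS: Tuple[float, float] = (1e-6, 2.0)

#: Fitting bounds for the softmax temperature (euros).
BETA_BOUNDS: Tuple[float, float] = (1e-3, 1e3)

#: Probabilities are clipped to [EPS, 1-EPS] before taking logs.
EPS: float = 1e-9

#: Convergence tolerance on the negative log-likelihood.
NLL_TOL: float = 1e-8


def subjective_value(
    option: Union[DelayedOption, Tuple[float, float]],
    k: float,
) -> float:
    """Discounted present value of a delayed reward.

    Parameters
    ----------
    option
        ``DelayedOption`` or ``(amount, delay)`` pair (euros, days).
    k
        Hyperbolic discount rate per day, ``k >= 0``.

    Returns
    -------
    float
        ``amount / (1 + k * delay)`` in euros.
    """
    if isinstance(option, DelayedOption):
        amount, delay = option.amount, option.delay
    else:
        amount, delay = option
    if k < 0:
        raise ValueError(f"discount rate must be non-negative, got {k}")
    if amount <= 0:
        raise ValueError(f"amount must be positive, got {amount}")
    if delay < 0:
        raise ValueError(f"delay must be non-negative, got {delay}")
    return amount / (1.0 + k * delay)


def choice_probability(sv_delayed: float, sv_immediate: float, beta: float):
    """Softmax probability of choosing the delayed option.

    ``P = logistic((sv_delayed - sv_immediate) / beta)`` with temperature
    ``beta > 0``; equal values give exactly 0.5 and the probability
    approaches a step function as ``beta -> 0``.
    """
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    return expit((np.asarray(sv_delayed) - np.asarray(sv_immediate)) / beta)


def _extract_arrays(
    trials: Union[Sequence[ChoiceTrial], pd.DataFrame],
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(amounts, delays, chose_delayed, conditions) from either container."""
    if isinstance(trials, pd.DataFrame):
        if len(trials) == 0:
            raise ValueError("empty trial table")
        amounts = trials["amount_eur"].to_numpy(dtype=float)
        delays = trials["delay_days"].to_numpy(dtype=float)
        chose = (trials["choice"].to_numpy() == "delayed")
        conditions = trials["condition"].to_numpy()
    else:
        trials = list(trials)
        if not trials:
            raise ValueError("empty trial list")
        amounts = np.array([t.option.amount for t in trials], dtype=float)
        delays = np.array([t.option.delay for t in trials], dtype=float)
        chose = np.array([t.choice == "delayed" for t in trials])
        conditions = np.array([t.condition for t in trials])
    return amounts, delays, chose, conditions


def _nll_array(
    k: float,
    beta: float,
    amounts: np.ndarray,
    delays: np.ndarray,
    chose_delayed: np.ndarray,
    ref_amount: float,
) -> Tuple[float, int]:
    """Negative log-likelihood plus count of clipped probabilities."""
    sv = amounts / (1.0 + k * delays)
    p_delayed = expit((sv - ref_amount) / beta)
    p_obs = np.where(chose_delayed, p_delayed, 1.0 - p_delayed)
    n_clipped = int(np.sum((p_obs < EPS) | (p_obs > 1.0 - EPS)))
    p_obs = np.clip(p_obs, EPS, 1.0 - EPS)
    return float(-np.sum(np.log(p_obs))), n_clipped


def negative_log_likelihood(
    k: float,
    beta: float,
    trials: Union[Sequence[ChoiceTrial], pd.DataFrame],
    ref: ImmediateReference = ImmediateReference(),
    *,
    require_single_condition: bool = True,
) -> float:
    """Negative log-likelihood of observed choices under (k, beta).

    Fits are per experimental condition, so by default the call refuses
    trial sets that mix conditions; pass
    ``require_single_condition=False`` for pooled fits where the caller
    has already decided the conditions share parameters.
    """
    if k < 0:
        raise ValueError(f"discount rate must be non-negative, got {k}")
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    amounts, delays, chose, conditions = _extract_arrays(trials)
    if require_single_condition and len(np.unique(conditions)) > 1:
        raise ValueError(
            "trials mix conditions "
            f"{sorted(np.unique(conditions))}; fits are per condition "
            "(pass require_single_condition=False for a pooled fit)"
        )
    nll, _ = _nll_array(k, beta, amounts, delays, chose, ref.amount)
    return nll


def _grid_starts(n_k: int = 8, n_beta: int = 8) -> np.ndarray:
    ks = np.geomspace(K_BOUNDS[0], K_BOUNDS[1], n_k)
    betas = np.geomspace(BETA_BOUNDS[0], BETA_BOUNDS[1], n_beta)
    kk, bb = np.meshgrid(ks, betas, indexing="ij")
    return np.column_stack([kk.ravel(), bb.ravel()])


def fit_mle(
    trials: Union[Sequence[ChoiceTrial], pd.DataFrame],
    ref: ImmediateReference = ImmediateReference(),
    *,
    k_bounds: Tuple[float, float] = K_BOUNDS,
    beta_bounds: Tuple[float, float] = BETA_BOUNDS,
    grid_shape: Tuple[int, int] = (8, 8),
    require_single_condition: bool = True,
) -> DiscountParams:
    """Maximum-likelihood (k, beta) for one subject × condition.

    Runs a bounded quasi-Newton (L-BFGS-B) refinement from every node of a
    log-spaced ``grid_shape`` start grid and keeps the best optimum.

    Trial sets in which only one choice type occurs carry no information
    about where the indifference point lies; these return the relevant
    bound of ``k_bounds`` (lower bound for an always-delayed chooser, upper
    bound for an always-immediate one) with ``converged=False`` and a
    warning rather than raising.
    """
    amounts, delays, chose, conditions = _extract_arrays(trials)
    if require_single_condition and len(np.unique(conditions)) > 1:
        raise ValueError(
            f"trials mix conditions {sorted(np.unique(conditions))}; "
            "fits are per condition"
        )
    n = len(amounts)
    if n < 12:
        warnings.warn(
            f"only {n} trials; estimates will be unstable", stacklevel=2
        )

    if chose.all() or (~chose).all():
        # Degenerate choice vector: the likelihood is monotone in k and the
        # optimizer would silently run into a bound; make that explicit.
        k_hat = k_bounds[0] if chose.all() else k_bounds[1]
        beta_hat = beta_bounds[0]
        nll, n_clip = _nll_array(k_hat, beta_hat, amounts, delays, chose, ref.amount)
        warnings.warn(
            "all choices are of one type; returning boundary estimate",
            stacklevel=2,
        )
        return DiscountParams(
            k=k_hat, beta=beta_hat, nll=nll, n_trials=n,
            converged=False, n_clipped=n_clip,
        )

    def objective(theta: np.ndarray) -> float:
        nll, _ = _nll_array(theta[0], theta[1], amounts, delays, chose, ref.amount)
        return nll

    best = None
    bounds = [k_bounds, beta_bounds]
    for start in _grid_starts(*grid_shape):
        res = minimize(
            objective, start, method="L-BFGS-B", bounds=bounds,
            options={"ftol": NLL_TOL, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    k_hat, beta_hat = float(best.x[0]), float(best.x[1])
    nll, n_clip = _nll_array(k_hat, beta_hat, amounts, delays, chose, ref.amount)
    return DiscountParams(
        k=k_hat, beta=beta_hat, nll=nll, n_trials=n,
        converged=bool(best.success), n_clipped=n_clip,
    )


def transform_k(k):
    """Square-root transform of the discount rate.

    Applied before group statistics to reduce the skew of the k
    distribution; monotone, with 0 mapping to 0.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("discount rate must be non-negative")
    out = np.sqrt(k)
    return float(out) if out.ndim == 0 else out


def indifference_amount(
    k: float, delay: int, ref: ImmediateReference = ImmediateReference()
) -> float:
    """Delayed amount whose subjective value equals the immediate reward.

    The algebraic inverse of :func:`subjective_value`:
    ``A* = ref.amount * (1 + k * delay)``, so that
    ``subjective_value((A*, delay), k) == ref.amount`` exactly.
    """
    if k < 0:
        raise ValueError(f"discount rate must be non-negative, got {k}")
    if delay < 0:
        raise ValueError(f"delay must be non-negative, got {delay}")
    return ref.amount * (1.0 + k * delay)
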