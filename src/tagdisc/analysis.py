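"""Cohort-level statistics for the episodic-tag discounting analysis.

Per-subject softmax-hyperbola fits per condition (plus a pooled "tag" fit
over both episodic conditions), the repeated-measures condition ANOVA on
sqrt-k, paired t tests, and covariate-adjusted (partial) correlations used
to relate attentional control to the tag-effect with gender as a covariate
of no interest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import fit_mle, transform_k
from .scores import filter_singleton_trials, singleton_score
from .types import CONDITIONS, CohortDataset, ImmediateReference, TAG, TAG_CONDITIONS

__all__ = [
    "fit_all_subjects",
    "summary_table",
    "tag_effect",
    "rm_anova",
    "paired_t",
    "covariate_adjusted_correlation",
    "analyze_cohort",
]


def fit_all_subjects(
    cohort: CohortDataset,
    *,
    ref: ImmediateReference = ImmediateReference(),
) -> pd.DataFrame:
    """Per-condition and pooled-tag MLE fits for every subject.

    Returns one row per subject with ``k_<cond>``, ``sqrt_k_<cond>``,
    ``beta_<cond>`` and ``converged_<cond>`` for the three task conditions
    plus the pooled ``tag`` fit (a single likelihood over the concatenated
    familiar + unfamiliar trials, not an average of the two fits).
    Subjects whose fit hits a degenerate choice vector are retained with
    ``converged_<cond> = False``.  Singleton score, memory score and gender
    are merged in when the cohort carries the corresponding tables.
    """
    if cohort.choices is None:
        raise ValueError("cohort has no choice trials; simulate with include_trials=True")
    rows = []
    for sid, trials in cohort.choices.groupby("subject_id"):
        row: dict = {"subject_id": sid}
        for cond in CONDITIONS:
            sub = trials[trials["condition"] == cond]
            if len(sub) == 0:
                raise ValueError(f"subject {sid} has no {cond} trials")
            fit = fit_mle(sub, ref)
            row[f"k_{cond}"] = fit.k
            row[f"beta_{cond}"] = fit.beta
            row[f"converged_{cond}"] = fit.converged
        pooled = trials[trials["condition"].isin(TAG_CONDITIONS)]
        fit = fit_mle(pooled, ref, require_single_condition=False)
        row[f"k_{TAG}"] = fit.k
        row[f"beta_{TAG}"] = fit.beta
        row[f"converged_{TAG}"] = fit.converged
        rows.append(row)
    fits = pd.DataFrame(rows)
    for cond in (*CONDITIONS, TAG):
        fits[f"sqrt_k_{cond}"] = transform_k(fits[f"k_{cond}"].to_numpy())

    if cohort.attention is not None:
        scores = []
        for sid, records in cohort.attention.groupby("subject_id"):
            valid, _ = filter_singleton_trials(records)
            scores.append({"subject_id": sid, "singleton_score": singleton_score(valid)})
        fits = fits.merge(pd.DataFrame(scores), on="subject_id", how="left")
    extra = [c for c in ("memory_score", "gender") if c in cohort.truths.columns]
    if extra:
        fits = fits.merge(
            cohort.truths[["subject_id", *extra]], on="subject_id", how="left"
        )
    return fits


def summary_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Median/IQR of k, beta (and sqrt-k) per condition row.

    Shaped like the study's model-characteristics table: one row each for
    control, pooled tag, familiar and unfamiliar.
    """
    rows = []
    for cond in ("control", TAG, "familiar", "unfamiliar"):
        entry = {"condition": cond}
        for param in ("k", "beta", "sqrt_k"):
            vals = summaries[f"{param}_{cond}"].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            entry[f"{param}_median"] = med
            entry[f"{param}_iqr"] = q3 - q1
        rows.append(entry)
    return pd.DataFrame(rows)


def tag_effect(summaries: pd.DataFrame) -> np.ndarray:
    """Per-subject tag-effect: sqrt-k (pooled tag) minus sqrt-k (control)."""
    return (
        summaries[f"sqrt_k_{TAG}"].to_numpy(dtype=float)
        - summaries["sqrt_k_control"].to_numpy(dtype=float)
    )


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: Optional[float] = None

    def __iter__(self):
        return iter((self.F, self.df1, self.df2, self.p))


def rm_anova(
    matrix,
    *,
    greenhouse_geisser: bool = False,
) -> AnovaResult:
    """One-way repeated-measures ANOVA across conditions.

    ``matrix`` is subjects x conditions (complete, n >= 3 subjects).  The F
    statistic is built from sums of squares: condition SS over the
    condition-by-subject interaction SS, with df = (c-1, (c-1)(n-1)).  No
    sphericity correction by default; ``greenhouse_geisser=True`` scales
    both dfs by the Greenhouse-Geisser epsilon when computing p.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("matrix must be subjects x conditions")
    if np.isnan(X).any():
        raise ValueError("missing cells in the condition matrix")
    n, c = X.shape
    if n < 3 or c < 2:
        raise ValueError(f"need >= 3 subjects and >= 2 conditions, got {X.shape}")
    grand = X.mean()
    cond_means = X.mean(axis=0)
    subj_means = X.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    resid = X - cond_means[None, :] - subj_means[:, None] + grand
    ss_err = np.sum(resid**2)
    df1 = c - 1
    df2 = (c - 1) * (n - 1)
    if ss_err == 0:
        F = 0.0 if ss_cond == 0 else math.inf
        return AnovaResult(F=F, df1=df1, df2=df2, p=1.0 if F == 0 else 0.0)
    F = (ss_cond / df1) / (ss_err / df2)
    eps = None
    if greenhouse_geisser:
        S = np.cov(X, rowvar=False)
        mean_diag = np.trace(S) / c
        eps = (c * mean_diag - S.mean()) ** 2 / (
            (c - 1) * (np.sum(S**2) - 2 * c * np.sum(S.mean(axis=1) ** 2)
                       + c**2 * S.mean() ** 2)
        )
        eps = float(np.clip(eps, 1.0 / (c - 1), 1.0))
        p = float(stats.f.sf(F, df1 * eps, df2 * eps))
    else:
        p = float(stats.f.sf(F, df1, df2))
    return AnovaResult(F=float(F), df1=df1, df2=df2, p=p, gg_epsilon=eps)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def paired_t(a, b) -> TTestResult:
    """Paired t test on the element-wise differences (df = n - 1).

    Zero-variance non-zero differences yield an infinite t with p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=math.copysign(math.inf, d.mean()), df=df, p=0.0)
    t = d.mean() / (sd / math.sqrt(n))
    p = float(2 * stats.t.sf(abs(t), df))
    return TTestResult(t=float(t), df=df, p=p)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    df: int
    n_covariates: int

    def __iter__(self):
        return iter((self.r, self.p))


def covariate_adjusted_correlation(
    x,
    y,
    covariates=None,
) -> CorrelationResult:
    """Partial Pearson correlation after linear removal of covariates.

    Both ``x`` and ``y`` are residualized on an intercept plus the
    covariate columns; the Pearson correlation of the residuals is tested
    on df = n - 2 - (number of covariates).  With no covariates this is
    the plain Pearson correlation.  Constant covariate columns are
    absorbed by the intercept; genuinely rank-deficient covariate sets and
    covariates that absorb all variance of x or y raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    n = len(x)
    if covariates is None:
        Z = np.ones((n, 1))
        n_cov = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
        # constant columns carry no information beyond the intercept;
        # drop them rather than flagging the design as rank deficient
        C = C[:, C.std(axis=0) > 0]
        Z = np.column_stack([np.ones(n), C])
        n_cov = C.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError(f"not enough observations (df = {df})")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # degenerate when a covariate absorbs (numerically) all variance
    for resid, orig in ((rx, x), (ry, y)):
        scale = float(np.sum((orig - orig.mean()) ** 2))
        if float(resid @ resid) <= 1e-12 * max(scale, 1e-300):
            raise ValueError("zero residual variance: correlation undefined")
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return CorrelationResult(r=r, p=0.0, df=df, n_covariates=n_cov)
    t = r * math.sqrt(df / (1.0 - r**2))
    p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(r=r, p=p, df=df, n_covariates=n_cov)


def analyze_cohort(
    cohort: CohortDataset,
    *,
    ref: ImmediateReference = ImmediateReference(),
) -> tuple[dict, pd.DataFrame]:
    """End-to-end cohort analysis: fits, condition ANOVA, control correlation.

    Returns ``(report, summaries)``: a JSON-serializable report with the
    per-condition summary table, the repeated-measures condition ANOVA on
    sqrt-k and the gender-adjusted partial correlation between the
    singleton score and the per-subject tag-effect, plus the per-subject
    summary frame it was computed from.
    """
    summaries = fit_all_subjects(cohort, ref=ref)
    matrix = summaries[[f"sqrt_k_{c}" for c in CONDITIONS]].to_numpy()
    anova = rm_anova(matrix)
    report = {
        "n_subjects": int(len(summaries)),
        "summary_table": summary_table(summaries).to_dict(orient="records"),
        "rm_anova": {"F": anova.F, "df1": anova.df1, "df2": anova.df2, "p": anova.p},
    }
    if "singleton_score" in summaries.columns and "gender" in summaries.columns:
        gender = (summaries["gender"] == "m").astype(float).to_numpy()
        try:
            corr = covariate_adjusted_correlation(
                summaries["singleton_score"].to_numpy(), tag_effect(summaries),
                gender,
            )
            report["singleton_vs_tag_effect"] = {
                "r": corr.r, "p": corr.p, "df": corr.df,
                "covariates": ["gender"],
            }
        except ValueError as exc:
            # e.g. cohorts too small for an adjusted correlation
            report["singleton_vs_tag_effect"] = {"error": str(exc)}
    return report, summaries
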