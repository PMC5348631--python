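# Methods

## Choice model

Intertemporal choices are modelled as a two-stage process. A delayed
reward of amount *A* euros at delay *D* days is valued by the Mazur
hyperbola

    SV(A, D; k) = A / (1 + k·D),

with *k* ≥ 0 the discount rate per day, and compared with a fixed
immediate reward of 20 € (never shown on screen in the task this models).
The delayed option is chosen with softmax probability

    P(delayed) = 1 / (1 + exp(−(SV − 20) / β)).

**β is a temperature** (units: euros of subjective-value difference per
logit): larger β means noisier, more stochastic choice, and β → 0
approaches a deterministic chooser. Much of the literature writes the
softmax with an *inverse* temperature multiplying the value difference;
the two conventions convert as β_temp = 1/β_inv, and absolute β values are
not comparable across conventions. The temperature convention is used
here so that "larger β = more decision noise" reads literally.

### Fitting

(k, β) are estimated per subject × condition by maximum likelihood:

- bounds k ∈ [10⁻⁶, 2] per day, β ∈ [10⁻³, 10³] € — generous around the
  plausible range (group medians in aging cohorts sit near k ≈ 0.08/day,
  β ≈ 2–3 €);
- L-BFGS-B refinement started from every node of an 8×8 log-spaced grid
  over the bounded box, keeping the best optimum (ftol 10⁻⁸ on the NLL);
- choice probabilities clipped to [10⁻⁹, 1 − 10⁻⁹] before logs so the NLL
  stays finite; clipping events are counted and reported in the fit
  metadata;
- trial sets containing only one choice type carry no information about
  the indifference point: the fit returns the relevant k bound (lower for
  an always-delayed chooser, upper for always-immediate) with
  `converged=False` and a warning rather than raising, mirroring what an
  unconstrained optimizer would do silently;
- fewer than 12 trials triggers an instability warning.

√k is used for all group statistics, compensating the right skew of
discount rates. The pooled "tag" parameter refits a single likelihood on
the concatenated familiar + unfamiliar trials rather than averaging the
two per-condition fits, since one likelihood uses all trials coherently.

## Adaptive design

The schedule builder inverts the hyperbola: for a pretest rate *k*, the
indifference amount at delay *D* is A\* = 20(1 + kD). Each of six delay
pairs ([1,2], [6,7], [13,15], [28,32], [85,95], [170,190] days) is crossed
with a six-rung amount ladder at symmetric offsets ±10 %, ±25 %, ±45 % of
A\* — spanning from near the indifference point to near the extremes while
keeping symmetry — rounded to half euros and clamped into [20.5, 79.5] €.
Collisions created by clamping/rounding are nudged apart in 0.5 € steps,
outward where the bounds allow and inward at a bound. Per trial, the
delay is drawn uniformly from its pair; each block holds the full 6×6
crossing (36 trials), shuffled. A session is six blocks, two adjacent
blocks per condition, condition order randomized; on episodic trials the
two social partners alternate deterministically. Identical (k, seed)
reproduce a byte-identical schedule.

### The 50 % design intention and its truncation

Symmetric amounts about A\* make a chooser with the construction k
indifferent on average, targeting a 50 % delayed-choice rate. This holds
exactly only where the full ladder fits inside the amount range, i.e.
20.5/0.55 ≤ A\* ≤ 79.5/1.45 (≈ 37–55 €). No single k satisfies this at
both 1-day and 190-day delays, so truncation is intrinsic, and at
realistic rates it is severe: at k = 0.085/day the indifference amounts of
the [85,95] and [170,190] pairs are ≈ 150–340 €, far above the 79.5 € cap,
so every amount at those delays is unattractive (ΔSV ≤ −10 €; P ≤ 0.006 at
β = 2) and the session-wide delayed-choice proportion is capped near 2/3
of 50 %. Measured over 200 sessions it is ≈ 34 %. The truncation cuts the
other way at small k: below k ≈ 0.01 the 20.5 € floor binds at the 1–2-day
delays (A\* ≈ 20.2 € < 20.5 €) and pushes the proportion above 50 %
(≈ 60 % at k = 0.008). This is a property of the task's published design
numbers — its amount range versus its delay range and typical rates — not
of the implementation; an alternative ladder that shrinks offsets to fit
the bounds was evaluated and changes none of it, because the cap, not the
ladder shape, is binding.

## Synthetic cohorts

The generator draws, per subject: √k_control ~ Normal(0.29, 0.15)
(truncated to the fitting bounds; mean at √0.085), a tag-effect δ ~
Normal(−0.005, 0.08) in √k units (negative = less discounting under
episodic tags; default mean matches the near-null √0.082 − √0.085), and a
singleton score ~ Normal(71.34, 89.29) ms drawn jointly with δ at
correlation ρ (default −0.67). Each condition's √k truth adds independent
Normal(0, 0.03) session noise, so with δ ≡ 0 the three conditions are
exchangeable and the repeated-measures ANOVA is exactly calibrated. β is
lognormal (median 2.5 €, log-SD 0.6); gender is Bernoulli(9/22); the
memory covariate is Normal(47.5, 10.34).

Choice tables are simulated from the same hyperbola + softmax the fitting
assumes (RTs are lognormal dressing, not modelled). The visual-search
generator emits 4 blocks × 48 trials per condition, distractors on half
the trials, singleton targets on 8 % of flexible-condition trials
(replacing the distractor), base RT 850 ms, a 30 ms ability-independent
distractor cost in the strategic condition and that cost plus the
subject's ability term in the flexible condition, Gaussian trial noise
(SD 150 ms), responses capped at the 3 s window, errors (3 %) and
omissions (1.5 %) at spec rates. Interview tallies are Poisson per
category per event, with familiar/unfamiliar category means summing to
internal totals of 6.55/5.87 details (the time category contributes ~0);
rater 2 re-codes rater 1 with a symmetric ±1 perturbation per cell at
probability 0.25, which controls Cronbach's alpha.

What the generator does *not* emulate: within-subject drift or fatigue,
RT–choice coupling, non-hyperbolic discounting, heavy-tailed RTs,
block-order effects, or any neural quantity. Passing recovery tests
therefore show the estimators are consistent under the model's own
assumptions, not that real cohorts satisfy them.

## Group statistics

- **RM-ANOVA**: one-way within-subject F from sums of squares; condition
  df = c − 1, error df = (c − 1)(n − 1) (so F(2, 42) at n = 22). No
  sphericity correction by default (Greenhouse–Geisser available as an
  option) — with only three conditions and session noise iid by
  construction, sphericity holds for the synthetic cohorts.
- **Paired t**: standard t on differences, df = n − 1; zero-variance
  nonzero differences report an infinite t with p = 0.
- **Partial correlation**: both variables residualized on an intercept
  plus covariates via least squares; Pearson r of residuals tested on
  df = n − 2 − (#covariates). Constant covariate columns are absorbed by
  the intercept (dropped without counting toward df); genuinely
  rank-deficient covariate sets raise. Gender enters correlations as a
  binary indicator covariate; it is not modelled inside the RM-ANOVA.
- Degenerate inputs (residuals numerically zero after covariate removal,
  empty RT cells, zero total rater variance) raise informative errors
  rather than returning NaN.

## Problem sizes

Simulation-based checks run at: 200 sessions for the delayed-choice
percentage; 100 sessions across k ∈ [10⁻⁴, 1] (log-uniform) for amount
bounds; 50 random fixtures against a 200×200 (k, β) lattice for the
likelihood optimum; 100 subjects × 216 trials for √k recovery (Pearson
r ≈ 0.99, median bias < 0.01 under these conditions); 1000 null cohorts
(n = 22) for ANOVA calibration; 500 cohorts for recovery of ρ = −0.67.
These sizes give Monte-Carlo error comfortably below the tolerances they
are tested against.

## Known limitations

- Only the Mazur hyperbola is implemented (no exponential or
  quasi-hyperbolic alternatives), and estimation is per-subject ML, not
  hierarchical/Bayesian.
- The calibration and correlation-recovery checks run on generator truths;
  refitting every subject of thousands of cohorts would add estimation
  noise but no information about the statistics being checked.
- The interview reliability default (alpha controlled by a ±1
  perturbation) reproduces plausible agreement levels but not the full
  disagreement structure of human raters.
- The two-group young/old contrast is supported only as a synthetic
  comparison of cohorts generated at different tag-effect means.
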