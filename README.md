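# tagdisc

Modelling and analysis code for **episodic-tag delay discounting**
experiments: intertemporal choice tasks in which some delayed rewards are
paired with a concrete imagined future event (an "episodic tag", e.g.
meeting a particular person in a café on the delivery date) and compared
with standard discounting trials. The package is aimed at decision
neuroscientists who run or simulate such tasks and want a tested,
reproducible pipeline from trial construction to group statistics.

It provides, as an importable library:

- **Choice model** — hyperbolic discounting with softmax choice.
  A delayed reward of amount *A* (€) at delay *D* (days) has subjective
  value *SV = A / (1 + kD)* (Mazur hyperbola); the delayed option is chosen
  over the fixed immediate 20 € with probability
  *P = 1 / (1 + exp(−(SV − 20)/β))*. *k* (per day) indexes impatience; *β*
  (€) is a **temperature**: larger β = noisier choices. (*k*, β) are fit
  per subject × condition by maximum likelihood (multi-start bounded
  quasi-Newton), with the √k transform used for group statistics.
- **Adaptive design** — pretest *k* → per-delay indifference amounts
  *A\* = 20(1 + kD)* → six-amount ladders symmetric about *A\** (clamped to
  20.5–79.5 €, half-euro steps) → six 36-trial blocks (delays drawn from
  six fixed day-pairs; two adjacent blocks per condition, condition order
  randomized).
- **Synthetic cohorts** — per-subject (√k, tag-effect, β, singleton score,
  memory score, gender) truths with a configurable correlation between
  attentional control and the tag-effect, plus simulated choice,
  visual-search and interview tables for every downstream stage.
- **Behavioral scores** — the singleton attentional-control index
  (distractor-cost difference between a flexible- and a strategic-attention
  search condition) with trial filtering, and Autobiographical-Interview
  style internal/external detail tallies with Cronbach's-alpha inter-rater
  reliability.
- **Group statistics** — per-condition and pooled-tag fits, a
  repeated-measures condition ANOVA on √k, paired t tests, and
  covariate-adjusted (partial) correlations with gender as a covariate of
  no interest.

## Worked example

`examples/01_fit_discounting.py` builds a schedule for a subject with
pretest *k* = 0.085/day, simulates choices at (k = 0.085, β = 2) and
refits each condition:

```
true parameters: k = 0.085/day, beta = 2.0 EUR
condition       k_hat   sqrt_k  beta_hat      nll    n
control        0.0806   0.2839     2.114    18.76   72
familiar       0.0876   0.2959     0.939     9.94   72
unfamiliar     0.0847   0.2911     2.718    23.52   72
```

Each per-condition estimate lands close to the generating rate
(√0.085 ≈ 0.292) because the adaptive design concentrates amounts around
each delay's indifference point, where choices are most informative. The
other examples cover schedule construction, singleton scoring, interview
reliability and the full cohort pipeline (`examples/05_cohort_analysis.py`
prints a model-parameter summary table, the condition RM-ANOVA and the
gender-adjusted singleton/tag-effect partial correlation).

A thin CLI mirrors the pipeline stages:

```sh
tagdisc design --k 0.085 --seed 1 --out schedule.csv
tagdisc simulate --out cohort/            # synthetic cohort directory
tagdisc fit --choices cohort/choices.csv --out fits.csv
tagdisc score --attention cohort/attention.csv --out scores.json
tagdisc analyze --cohort cohort/ --out report.json
```

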