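"""Synthetic cohort generator: determinism, marginals, covariance structure."""

import numpy as np
import pandas as pd
import pytest

import tagdisc as td
from tagdisc.simulate import ALL_CATEGORIES, INTERNAL_CATEGORIES


class TestSimulateChoices:
    def test_same_seed_identical_choices(self, schedule):
        a = td.simulate_choices(schedule, 0.085, 2.0, rng=3)
        b = td.simulate_choices(schedule, 0.085, 2.0, rng=3)
        assert a.equals(b)

    def test_near_deterministic_at_tiny_beta(self, schedule):
        choices = td.simulate_choices(schedule, 0.085, 1e-3, rng=0)
        sv = choices["amount_eur"] / (1 + 0.085 * choices["delay_days"])
        attractive = sv > 20.5  # clear of the indifference point
        assert (choices.loc[attractive, "choice"] == "delayed").all()

    def test_half_rate_at_indifference(self):
        # 10^4 replicated trials exactly at dSV = 0 must come out 50 +/- 1.5%
        trials = pd.DataFrame({
            "block_index": 0, "trial_index": np.arange(10_000),
            "condition": "control", "partner_slot": 0,
            "delay_days": 10, "amount_eur": 40.0,  # indifference at k = 0.1
        })
        sch = td.TrialSchedule(trials=trials, condition_order=("control",) * 3,
                               k=0.1, seed=0)
        choices = td.simulate_choices(sch, 0.1, 2.0, rng=9)
        rate = (choices["choice"] == "delayed").mean()
        assert rate == pytest.approx(0.5, abs=0.015)

    def test_per_condition_rates(self, schedule):
        k_map = {"control": 0.2, "familiar": 0.001, "unfamiliar": 0.001}
        choices = td.simulate_choices(schedule, k_map, 1.0, rng=1)
        frac = choices.groupby("condition")["choice"].apply(
            lambda s: (s == "delayed").mean()
        )
        # patient conditions choose delayed far more often
        assert frac["familiar"] > frac["control"] + 0.2
        with pytest.raises(ValueError, match="missing conditions"):
            td.simulate_choices(schedule, {"control": 0.1}, 1.0, rng=1)


class TestCohortSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            td.CohortSpec(n_subjects=1)
        with pytest.raises(ValueError):
            td.CohortSpec(rho_singleton_tag=-1.5)
        with pytest.raises(ValueError):
            td.CohortSpec(familiar_rates={"bogus": 1.0})

    def test_defaults_emulate_cohort(self):
        spec = td.CohortSpec()
        assert spec.n_subjects == 22
        assert spec.rho_singleton_tag == pytest.approx(-0.67)


class TestSimulateTruths:
    def test_deterministic(self):
        spec = td.CohortSpec(seed=5)
        a = td.simulate_truths(spec, np.random.default_rng(5))
        b = td.simulate_truths(spec, np.random.default_rng(5))
        assert a.equals(b)

    def test_null_correlation(self):
        spec = td.CohortSpec(n_subjects=4000, rho_singleton_tag=0.0)
        truths = td.simulate_truths(spec, np.random.default_rng(0))
        r = np.corrcoef(truths["singleton_true"], truths["tag_effect_true"])[0, 1]
        assert abs(r) < 0.1

    def test_target_correlation_recovered(self):
        spec = td.CohortSpec(n_subjects=4000, rho_singleton_tag=-0.67)
        truths = td.simulate_truths(spec, np.random.default_rng(1))
        r = np.corrcoef(truths["singleton_true"], truths["tag_effect_true"])[0, 1]
        assert r == pytest.approx(-0.67, abs=0.05)

    def test_marginal_moments(self):
        spec = td.CohortSpec(n_subjects=10_000)
        truths = td.simulate_truths(spec, np.random.default_rng(2))
        assert truths["sqrt_k_control_true"].mean() == pytest.approx(0.29, abs=0.01)
        assert truths["singleton_true"].mean() == pytest.approx(71.34, abs=3.0)
        assert truths["singleton_true"].std() == pytest.approx(89.29, rel=0.05)
        assert np.median(truths["beta_true"]) == pytest.approx(2.5, rel=0.05)

    def test_zero_tag_effect_gives_exchangeable_conditions(self):
        spec = td.CohortSpec(n_subjects=8000, tag_effect_mean=0.0,
                             tag_effect_sd=0.0)
        truths = td.simulate_truths(spec, np.random.default_rng(3))
        diff = truths["sqrt_k_familiar_true"] - truths["sqrt_k_control_true"]
        assert abs(diff.mean()) < 3 * diff.std() / np.sqrt(len(diff))


class TestSingletonTrials:
    def test_noiseless_closure(self):
        spec = td.CohortSpec(rt_noise_sd_ms=0.0, error_rate=0.0, miss_rate=0.0)
        records = td.simulate_singleton_trials(71.34, spec, rng=0)
        valid, report = td.filter_singleton_trials(records)
        assert report.n_excluded == 0
        assert td.singleton_score(valid) == pytest.approx(71.34, abs=1e-9)

    def test_symmetric_costs_give_zero(self):
        spec = td.CohortSpec(rt_noise_sd_ms=0.0, error_rate=0.0, miss_rate=0.0)
        records = td.simulate_singleton_trials(0.0, spec, rng=0)
        assert td.singleton_score(records) == pytest.approx(0.0, abs=1e-9)

    def test_trial_counts_and_window(self):
        spec = td.CohortSpec()
        records = td.simulate_singleton_trials(70.0, spec, rng=4)
        counts = records.groupby("condition").size()
        assert counts[1] == counts[2] == 4 * 48
        assert not records.loc[records["condition"] == 1, "singleton_target"].any()
        assert records["rt_ms"].dropna().max() <= 3000.0

    def test_mean_recovered_score(self):
        # noise on: the score is unbiased for the injected cost difference
        spec = td.CohortSpec()
        scores = []
        rng = np.random.default_rng(6)
        for _ in range(200):
            records = td.simulate_singleton_trials(71.34, spec, rng)
            valid, _ = td.filter_singleton_trials(records)
            scores.append(td.singleton_score(valid))
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert np.mean(scores) == pytest.approx(71.34, abs=3 * se)

    def test_exclusion_rate_matches_spec(self):
        spec = td.CohortSpec(error_rate=0.0302, miss_rate=0.015)
        rng = np.random.default_rng(8)
        excluded = total = 0
        for _ in range(50):
            records = td.simulate_singleton_trials(70.0, spec, rng)
            _, report = td.filter_singleton_trials(records)
            excluded += report.n_excluded
            total += report.n_total
        rate = 100.0 * excluded / total
        se = 100.0 * np.sqrt(0.0452 * (1 - 0.0452) / total)
        assert rate == pytest.approx(4.52, abs=3 * se + 0.05)


class TestInterview:
    def test_zero_perturbation_alpha_one(self):
        spec = td.CohortSpec(rater_disagreement_prob=0.0)
        rows = pd.concat(
            [td.simulate_interview(spec, np.random.default_rng(s), subject_id=s)
             for s in range(10)],
            ignore_index=True,
        )
        internal = rows[rows["category"] != "external"]
        piv = (internal.groupby(["subject_id", "event_id", "rater"])["count"]
               .sum().unstack("rater"))
        assert td.cronbach_alpha(piv[1], piv[2]) == pytest.approx(1.0)

    def test_independent_raters_alpha_near_zero(self):
        rng = np.random.default_rng(10)
        r1 = rng.poisson(6.5, size=4000)
        r2 = rng.poisson(6.5, size=4000)
        assert abs(td.cronbach_alpha(r1, r2)) < 0.1

    def test_category_means_match_rates(self):
        spec = td.CohortSpec(rater_disagreement_prob=0.0)
        rows = pd.concat(
            [td.simulate_interview(spec, np.random.default_rng(100 + s),
                                   subject_id=s) for s in range(400)],
            ignore_index=True,
        )
        summary = td.tally_details(rows)
        fam = summary[summary["familiarity"] == "familiar"].set_index("measure")
        n_events = fam.loc["internal", "n_events"]
        se = np.sqrt(6.55 / n_events)
        assert fam.loc["internal", "mean"] == pytest.approx(6.55, abs=3 * se)
        assert fam.loc["event", "mean"] == pytest.approx(2.23, abs=0.3)
        unfam = summary[summary["familiarity"] == "unfamiliar"].set_index("measure")
        assert unfam.loc["internal", "mean"] == pytest.approx(5.87, abs=3 * se)


class TestSimulateCohort:
    def test_shapes_and_determinism(self, small_cohort):
        assert small_cohort.n_subjects == 5
        counts = small_cohort.choices.groupby("subject_id").size()
        assert (counts == 216).all()
        again = td.simulate_cohort(td.CohortSpec(n_subjects=5, seed=42))
        assert again.choices.equals(small_cohort.choices)
        assert again.truths.equals(small_cohort.truths)

    def test_truths_only_mode(self):
        cohort = td.simulate_cohort(td.CohortSpec(n_subjects=8, seed=1),
                                    include_trials=False)
        assert cohort.choices is None
        assert len(cohort.truths) == 8
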