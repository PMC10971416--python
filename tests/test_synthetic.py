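"""Generator invariants: task designs, cohorts, item responses, exclusions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cogmech import synthetic as syn


class TestTaskDesign:
    def test_default_reproduces_published_dimensions(self, default_design):
        assert default_design.n_trials == 44
        assert default_design.n_catch == 2
        assert len(np.unique(default_design.block)) == 4
        default_design.validate()

    def test_catch_trials_offer_max_reward_at_min_effort(self, default_design):
        catch = default_design.is_catch
        assert np.all(default_design.reward_hi[catch] == 7)
        assert np.all(default_design.effort_hi[catch] == 0.25)
        # catch trials sit in distinct blocks
        assert len(set(default_design.block[catch])) == default_design.n_catch

    def test_noncatch_trials_nondominated(self, default_design):
        reg = ~default_design.is_catch
        assert np.all(
            default_design.effort_hi[reg] > default_design.effort_lo[reg]
        )
        assert np.all(
            default_design.reward_hi[reg] > default_design.reward_lo[reg]
        )

    def test_custom_small_design(self):
        d = syn.generate_task_design(
            n_blocks=1, trials_per_block=3, n_catch=0, seed=5
        )
        assert d.n_trials == 3 and d.n_catch == 0

    def test_same_seed_identical(self):
        a = syn.generate_task_design(seed=9)
        b = syn.generate_task_design(seed=9)
        for f in ("reward_hi", "reward_lo", "effort_hi", "effort_lo"):
            np.testing.assert_array_equal(getattr(a, f), getattr(b, f))

    def test_degenerate_levels_raise(self):
        with pytest.raises(syn.DesignError):
            syn.generate_task_design(reward_levels=(5, 5))
        with pytest.raises(syn.DesignError):
            syn.generate_task_design(n_effort_levels=1)

    def test_attribution_design_invariants(self):
        d = syn.AttributionDesign()
        assert d.n_positive + d.n_negative == d.n_scenarios == 32
        with pytest.raises(syn.DesignError):
            syn.AttributionDesign(n_positive=10)


class TestRewardEffortCohort:
    def test_schema_and_determinism(self, default_design):
        cohort = syn.default_reward_effort_cohort(n_subjects=8, seed=2)
        a = syn.simulate_reward_effort_cohort(default_design, cohort)
        b = syn.simulate_reward_effort_cohort(default_design, cohort)
        pd.testing.assert_frame_equal(a, b)
        assert set(a.columns) == {
            "subject_id", "arm", "session", "block", "trial", "reward_hi",
            "reward_lo", "effort_hi", "effort_lo", "is_catch", "choice_hi",
            "rt_s",
        }
        assert set(a["session"]) == {1, 2}
        assert a.groupby("subject_id").size().eq(88).all()

    def test_extreme_reward_sensitivity_always_takes_higher_reward(
        self, default_design
    ):
        cohort = syn.default_reward_effort_cohort(
            n_subjects=4,
            true_group_means={"rewSens": (1e3, 1e3), "effSens": (0.0, 0.0)},
            subject_sd={"rewSens": 0.0, "effSens": 0.0},
            seed=1,
        )
        df = syn.simulate_reward_effort_cohort(default_design, cohort)
        assert df["choice_hi"].eq(1).all()

    def test_zero_sensitivities_give_chance_choice(self, default_design):
        cohort = syn.default_reward_effort_cohort(
            n_subjects=60,
            true_group_means={"rewSens": (0.0, 0.0), "effSens": (0.0, 0.0)},
            subject_sd={"rewSens": 0.0, "effSens": 0.0},
            seed=8,
        )
        df = syn.simulate_reward_effort_cohort(default_design, cohort)
        n = len(df)
        rate = df["choice_hi"].mean()
        assert abs(rate - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_positive_sensitivities_prefer_catch_dominant_option(self):
        # dominant option carries more reward for less effort, so any
        # subject with positive sensitivities should choose it above chance
        design = syn.generate_task_design(
            n_blocks=250, trials_per_block=2, n_catch=250, seed=3
        )
        cohort = syn.default_reward_effort_cohort(
            n_subjects=2,
            allocation=(0, 1),
            true_group_means={"rewSens": (0.8, 0.8), "effSens": (1.5, 1.5)},
            subject_sd={"rewSens": 0.0, "effSens": 0.0},
            seed=4,
        )
        df = syn.simulate_reward_effort_cohort(design, cohort)
        catch = df[(df["is_catch"] == 1) & (df["session"] == 1) & (df["subject_id"] == 0)]
        assert len(catch) == 250
        assert catch["choice_hi"].mean() > 0.5

    def test_cross_session_correlation_recovered(self, default_design):
        cohort = syn.default_reward_effort_cohort(
            n_subjects=500, cross_session_correlation=0.75, seed=10
        )
        df = syn.simulate_reward_effort_cohort(default_design, cohort)
        p = df.attrs["truth"]["params"]
        for k in ("rewSens", "effSens"):
            r = np.corrcoef(p[k][:, 0], p[k][:, 1])[0, 1]
            assert abs(r - 0.75) < 0.1

    def test_marginal_choice_rate_matches_closed_form(self):
        # one known-parameter subject, many trials: empirical rate within
        # 3 binomial SEs of the Bernoulli-logit probability per offer type
        from scipy.special import expit

        design = syn.generate_task_design(
            n_blocks=250, trials_per_block=40, n_catch=0, seed=6
        )
        cohort = syn.default_reward_effort_cohort(
            n_subjects=2,
            allocation=(0, 1),
            subject_sd={"rewSens": 0.0, "effSens": 0.0},
            seed=7,
        )
        df = syn.simulate_reward_effort_cohort(design, cohort)
        df = df[(df["session"] == 1) & (df["subject_id"] == 0)]
        logit = 0.8 * (df.reward_hi - df.reward_lo) - 1.5 * (
            df.effort_hi - df.effort_lo
        )
        p = expit(logit)
        n = len(df)
        expected = p.mean()
        se = np.sqrt(np.sum(p * (1 - p))) / n
        assert abs(df["choice_hi"].mean() - expected) < 3 * se

    def test_nonpsd_correlation_rejected(self):
        with pytest.raises(syn.DesignError):
            syn.default_reward_effort_cohort(cross_session_correlation=1.5)


class TestAttributionCohort:
    def test_schema_and_counts(self, small_attribution_df):
        df = small_attribution_df
        assert set(df.columns) == {
            "subject_id", "arm", "session", "trial", "valence",
            "choice_internal", "choice_global", "option_position", "rt_s",
        }
        per_cell = df.groupby(["subject_id", "session", "valence"]).size()
        assert set(per_cell) == {16}

    def test_neutral_trait_gives_even_endorsement(self):
        cohort = syn.default_attribution_cohort(
            n_subjects=60,
            true_group_means={p: (0.0, 0.0)
                              for p in syn.ATTRIBUTION_PARAMS},
            subject_sd={p: 0.0 for p in syn.ATTRIBUTION_PARAMS},
            seed=3,
        )
        df = syn.simulate_attribution_cohort(cohort=cohort)
        n = len(df)
        for col in ("choice_internal", "choice_global"):
            assert abs(df[col].mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_extreme_trait_saturates(self):
        cohort = syn.default_attribution_cohort(
            n_subjects=4,
            true_group_means={
                **{p: (50.0, 50.0) for p in syn.ATTRIBUTION_PARAMS}
            },
            subject_sd={p: 0.0 for p in syn.ATTRIBUTION_PARAMS},
            seed=3,
        )
        df = syn.simulate_attribution_cohort(cohort=cohort)
        assert df["choice_internal"].eq(1).all()
        assert df["choice_global"].eq(1).all()

    def test_cross_trait_correlation_induces_rate_correlation(self):
        cohort = syn.default_attribution_cohort(
            n_subjects=200, cross_trait_correlation=0.9, seed=5
        )
        df = syn.simulate_attribution_cohort(cohort=cohort)
        rates = df[df.session == 1].groupby("subject_id")[
            ["choice_internal", "choice_global"]
        ].mean()
        r = np.corrcoef(rates["choice_internal"], rates["choice_global"])[0, 1]
        assert r > 0.5

    def test_determinism(self):
        cohort = syn.default_attribution_cohort(n_subjects=5, seed=21)
        a = syn.simulate_attribution_cohort(cohort=cohort)
        b = syn.simulate_attribution_cohort(cohort=cohort)
        pd.testing.assert_frame_equal(a, b)


class TestItemResponses:
    def test_grm_middle_category_closed_form(self):
        # a=1, thresholds (-1, 1), trait 0: middle category probability is
        # the difference of two logistic CDFs at +-1
        p = syn.grm_category_probabilities(0.0, 1.0, (-1.0, 1.0))
        expected = 1 / (1 + np.exp(-1)) - 1 / (1 + np.exp(1))
        assert p.shape == (3,)
        assert abs(p[1] - expected) < 1e-12
        assert abs(p.sum() - 1.0) < 1e-12

    def test_grm_probabilities_normalize_on_random_grid(self, rng):
        for _ in range(50):
            theta = rng.normal(0, 2, size=7)
            a = float(rng.uniform(0.1, 3))
            kappa = np.sort(rng.normal(0, 2, size=4))
            kappa += np.arange(4) * 1e-6  # guard strict ordering
            p = syn.grm_category_probabilities(theta, a, kappa)
            assert np.all(p >= -1e-12)
            np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-10)

    def test_zero_discrimination_ignores_trait(self):
        bank = syn.ItemBank(
            (syn.Item("x1", "AMI", "A", 1e-9, (-1.0, 0.0, 1.0)),)
        )
        traits_lo = {"A": np.full(10_000, -3.0)}
        traits_hi = {"A": np.full(10_000, 3.0)}
        lo = syn.simulate_item_responses(traits_lo, bank, seed=1)
        hi = syn.simulate_item_responses(traits_hi, bank, seed=2)
        tab = np.array(
            [
                np.bincount(lo["response"], minlength=4),
                np.bincount(hi["response"], minlength=4),
            ]
        )
        _, p, _, _ = stats.chi2_contingency(tab)
        assert p > 0.01

    def test_extreme_trait_hits_top_category(self):
        bank = syn.default_item_banks()
        df = syn.simulate_item_responses(
            {"A": np.full(5, 60.0), "N": np.full(5, 60.0)}, bank, seed=0
        )
        for item in bank:
            sub = df[df["item_id"] == item.item_id]
            assert sub["response"].eq(item.n_categories - 1).all()

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(syn.DesignError):
            syn.Item("bad", "DAS", "N", 1.0, (1.0, -1.0))

    def test_default_banks_mirror_trait_composition(self):
        bank = syn.default_item_banks()
        a_items = bank.for_trait("A")
        n_items = bank.for_trait("N")
        assert len(a_items) == 8 and len(n_items) == 10
        assert sum(i.instrument == "AMI" for i in a_items) == 6
        assert sum(i.instrument == "PHQ9" for i in a_items) == 2
        assert sum(i.instrument == "DAS" for i in n_items) == 8


class TestExclusionRules:
    def test_one_of_two_catch_trials_suffices(self, default_design):
        cohort = syn.default_reward_effort_cohort(n_subjects=6, seed=13)
        df = syn.simulate_reward_effort_cohort(default_design, cohort)
        # subject 0: correct on exactly one catch trial -> retained
        catch_idx = df[(df.subject_id == 0) & (df.is_catch == 1)].index
        df.loc[catch_idx, "choice_hi"] = [1, 0, 1, 0]
        # subject 1: wrong on every catch trial -> excluded
        catch_idx = df[(df.subject_id == 1) & (df.is_catch == 1)].index
        df.loc[catch_idx, "choice_hi"] = 0
        filtered, report = syn.apply_exclusion_rules(df, "reward-effort")
        assert 0 in set(filtered["subject_id"])
        assert 1 not in set(filtered["subject_id"])
        assert report.excluded == {1: ["catch"]}

    def test_attribution_rt_rule_strict_boundary(self, small_attribution_df):
        df = small_attribution_df.copy()
        df.loc[df.subject_id == 2, "rt_s"] = 1.9
        df.loc[df.subject_id == 3, "rt_s"] = 2.0  # median exactly 2 s: out
        df.loc[df.subject_id == 4, "rt_s"] = 2.1
        filtered, report = syn.apply_exclusion_rules(df, "attribution")
        assert report.excluded.get(2) == ["rt"]
        assert report.excluded.get(3) == ["rt"]
        assert 4 in set(filtered["subject_id"])

    def test_position_rule_excludes_at_exactly_75_percent(self):
        cohort = syn.default_attribution_cohort(n_subjects=3, seed=6)
        df = syn.simulate_attribution_cohort(cohort=cohort)
        rows = df[df.subject_id == 1].index
        n = len(rows)
        k = int(np.ceil(0.75 * n))
        filler = np.tile([1, 2, 3], n)[: n - k]
        df.loc[rows[:k], "option_position"] = 0
        df.loc[rows[k:], "option_position"] = filler
        filtered, report = syn.apply_exclusion_rules(df, "attribution")
        assert "position" in report.excluded.get(1, [])

    def test_missing_columns_raise_schema_error(self):
        with pytest.raises(KeyError):
            syn.apply_exclusion_rules(
                pd.DataFrame({"subject_id": [1]}), "reward-effort"
            )
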