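"""Reward-effort model: elementary operations, likelihood oracle, fitting."""

import numpy as np
import pandas as pd
import pytest

from cogmech import synthetic as syn
from cogmech.reward_effort import (
    PriorConfig,
    choice_probability,
    dataset_loglik,
    fit_reward_effort,
    intervention_effect_summary,
    option_value,
)
from cogmech.results import ConvergenceWarning, effect_from_draws
from cogmech.sampling import SamplerConfig


class TestElementaryOps:
    @pytest.mark.parametrize(
        "rew,eff,r,e,expected",
        [
            (1.0, 1.0, 5, 0.5, 4.5),
            (0.0, 0.0, 7, 0.95, 0.0),
            (2.0, 3.0, 7, 0.95, 11.15),
        ],
    )
    def test_option_value_substitution(self, rew, eff, r, e, expected):
        assert option_value(rew, eff, r, e) == pytest.approx(expected)

    def test_choice_probability_symmetry_and_closed_form(self):
        assert choice_probability(2.0, 2.0) == pytest.approx(0.5)
        assert choice_probability(np.log(3), 0.0) == pytest.approx(0.75)

    def test_choice_probability_saturates_without_overflow(self):
        p = choice_probability(50.0, 0.0)
        assert 1.0 - p <= 1e-20
        assert np.isfinite(choice_probability(-1e6, 1e6))

    def test_value_shift_invariance(self, rng):
        # adding a constant to both options leaves the choice probability
        # unchanged: only the value difference matters
        v_hi, v_lo = rng.normal(size=(2, 100))
        shift = rng.normal(size=100) * 10
        np.testing.assert_allclose(
            choice_probability(v_hi, v_lo),
            choice_probability(v_hi + shift, v_lo + shift),
            rtol=1e-12,
        )


class TestDatasetLoglik:
    def _params(self, sids, rew, eff):
        rows = []
        for sid in sids:
            for s in (1, 2):
                rows.append(
                    {"subject_id": sid, "session": s, "rewSens": rew,
                     "effSens": eff}
                )
        return pd.DataFrame(rows)

    def test_chance_model_gives_t_log_half(self, small_choice_df):
        df = small_choice_df
        params = self._params(df["subject_id"].unique(), 0.0, 0.0)
        t = len(df[df["is_catch"] == 0])
        ll = dataset_loglik(params, df)
        assert ll == pytest.approx(t * np.log(0.5), rel=1e-12)

    def test_single_trial_probability(self):
        df = pd.DataFrame(
            {
                "subject_id": [0],
                "session": [1],
                "reward_hi": [4],
                "reward_lo": [3],
                "effort_hi": [0.5],
                "effort_lo": [0.25],
                "is_catch": [0],
                "choice_hi": [1],
            }
        )
        params = self._params([0], np.log(3), 0.0)
        # logit = log(3) * 1 -> p = 0.75
        assert dataset_loglik(params, df) == pytest.approx(np.log(0.75))

    def test_agreement_with_brute_force_loop(self, small_choice_df, rng):
        df = small_choice_df[small_choice_df["subject_id"].isin([0, 1, 2])]
        params = self._params([0, 1, 2], 0.7, 1.2)
        expected = 0.0
        for _, row in df[df["is_catch"] == 0].iterrows():
            v_hi = 0.7 * row.reward_hi - 1.2 * row.effort_hi
            v_lo = 0.7 * row.reward_lo - 1.2 * row.effort_lo
            p = 1.0 / (1.0 + np.exp(-(v_hi - v_lo)))
            expected += np.log(p if row.choice_hi else 1 - p)
        assert dataset_loglik(params, df) == pytest.approx(expected, rel=1e-9)

    def test_missing_subject_raises(self, small_choice_df):
        params = self._params([0], 1.0, 1.0)
        with pytest.raises(KeyError):
            dataset_loglik(params, small_choice_df)


class TestEffectSummary:
    def test_degenerate_draws(self):
        e = effect_from_draws("phi", np.full(100, -0.3))
        assert e.mean == pytest.approx(-0.3)
        assert (e.ci_low, e.ci_high) == (pytest.approx(-0.3),
                                         pytest.approx(-0.3))
        assert e.excludes_zero

    def test_symmetric_draws_do_not_exclude_zero(self, rng):
        e = effect_from_draws("phi", rng.normal(0, 1, 4000))
        assert not e.excludes_zero

    def test_ci_matches_independent_quantiles(self, rng):
        draws = rng.normal(0.2, 0.5, 4000)
        e = effect_from_draws("phi", draws, level=0.90)
        assert e.ci_low == pytest.approx(np.quantile(draws, 0.05))
        assert e.ci_high == pytest.approx(np.quantile(draws, 0.95))


@pytest.fixture(scope="module")
def quick_fit_and_data():
    design = syn.generate_task_design(seed=1)
    cohort = syn.default_reward_effort_cohort(
        n_subjects=24,
        true_intervention_effect={"rewSens": 0.0, "effSens": -0.6},
        seed=42,
    )
    df = syn.simulate_reward_effort_cohort(design, cohort)
    mcmc = SamplerConfig(n_chains=2, n_iter=400, n_warmup=1200,
                         steps_per_iter=4, group_substeps=2, seed=0)
    fit = fit_reward_effort(df, mcmc=mcmc, check=False)
    return fit, df


class TestFitting:
    def test_draw_shapes_and_names(self, quick_fit_and_data):
        fit, df = quick_fit_and_data
        assert fit.draws["mu"].shape == (2, 400, 2, 2)
        assert fit.draws["phi_int"].shape == (2, 400, 2)
        assert fit.draws["subj"].shape[2:] == (24, 2, 2)
        s = fit.summary()
        assert "mu[effSens,2]" in s.index and "R[rewSens]" in s.index

    def test_seeded_determinism(self, quick_fit_and_data):
        fit, df = quick_fit_and_data
        mcmc = SamplerConfig(n_chains=2, n_iter=50, n_warmup=200,
                             steps_per_iter=2, seed=3)
        a = fit_reward_effort(df, mcmc=mcmc, check=False)
        b = fit_reward_effort(df, mcmc=mcmc, check=False)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_group_means_recovered_roughly(self, quick_fit_and_data):
        fit, _ = quick_fit_and_data
        s = fit.summary()
        # generous bands: small cohort, short chains
        assert abs(s.loc["mu[rewSens,1]", "mean"] - 0.8) < 0.4
        assert abs(s.loc["mu[effSens,1]", "mean"] - 1.5) < 0.8

    def test_intervention_summary_fields(self, quick_fit_and_data):
        fit, _ = quick_fit_and_data
        effects = intervention_effect_summary(fit, level=0.90)
        assert [e.parameter for e in effects] == [
            "phi_int[rewSens]", "phi_int[effSens]",
        ]
        for e in effects:
            assert e.ci_low <= e.mean <= e.ci_high
            assert e.smd is not None

    def test_single_session_data_rejected(self, small_choice_df):
        df = small_choice_df[small_choice_df["session"] == 1]
        with pytest.raises(ValueError):
            fit_reward_effort(df)

    def test_prior_sample_roundtrip(self, small_choice_df):
        # prior draws land in the support of the prior density
        from cogmech.reward_effort import RewardEffortTarget

        target = RewardEffortTarget(
            small_choice_df, priors=PriorConfig.pilot_informed()
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            g, z = target.sample_prior(rng)
            assert np.isfinite(target.group_log_prior(g))
            assert np.all(np.isfinite(target.per_subject_loglik(g, z)))
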