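"""Attribution model: link, likelihood oracle, fitting, summaries."""

import numpy as np
import pandas as pd
import pytest

from cogmech import synthetic as syn
from cogmech.attribution import (
    attribution_intervention_summary,
    attribution_loglik,
    attribution_probability,
    endorsement_summary,
    fit_attribution,
)
from cogmech.sampling import SamplerConfig


class TestLink:
    def test_symmetry_and_closed_form(self):
        assert attribution_probability(0.0) == pytest.approx(0.5)
        assert attribution_probability(np.log(9)) == pytest.approx(0.9)

    def test_monotone_on_grid(self):
        grid = np.linspace(-6, 6, 101)
        p = attribution_probability(grid)
        assert np.all(np.diff(p) > 0)
        assert np.all((p > 0) & (p < 1))


class TestLoglik:
    def _traits(self, sids, th_int, th_glob):
        rows = []
        for sid in sids:
            for s in (1, 2):
                for v in ("pos", "neg"):
                    rows.append(
                        {
                            "subject_id": sid,
                            "session": s,
                            "valence": v,
                            "theta_internal": th_int,
                            "theta_global": th_glob,
                        }
                    )
        return pd.DataFrame(rows)

    def test_neutral_traits_give_two_codes_log_half_each(
        self, small_attribution_df
    ):
        df = small_attribution_df[small_attribution_df.subject_id == 0]
        df = df[df.session == 1]
        traits = self._traits([0], 0.0, 0.0)
        # 32 scenarios x 2 binary codes
        assert attribution_loglik(traits, df) == pytest.approx(
            64 * np.log(0.5)
        )

    def test_single_trial_composition(self):
        df = pd.DataFrame(
            {
                "subject_id": [0],
                "session": [1],
                "valence": ["neg"],
                "choice_internal": [1],
                "choice_global": [1],
            }
        )
        # p(internal)=0.8, p(global)=0.5
        traits = self._traits([0], np.log(4), 0.0)
        assert attribution_loglik(traits, df) == pytest.approx(
            np.log(0.8) + np.log(0.5)
        )

    def test_agreement_with_brute_force_loop(self, small_attribution_df):
        from scipy.special import expit

        df = small_attribution_df[
            small_attribution_df.subject_id.isin([0, 1])
        ]
        traits = self._traits([0, 1], 0.4, -0.7)
        expected = 0.0
        for _, row in df.iterrows():
            for th, y in ((0.4, row.choice_internal), (-0.7, row.choice_global)):
                p = expit(th)
                expected += np.log(p if y else 1 - p)
        assert attribution_loglik(traits, df) == pytest.approx(
            expected, rel=1e-9
        )

    def test_missing_cell_raises(self, small_attribution_df):
        traits = self._traits([0], 0.0, 0.0)
        with pytest.raises(KeyError):
            attribution_loglik(traits, small_attribution_df)


@pytest.fixture(scope="module")
def quick_attr_fit():
    cohort = syn.default_attribution_cohort(
        n_subjects=20,
        true_intervention_effect={
            "internal_pos": 0.0, "global_pos": 0.0,
            "internal_neg": -0.8, "global_neg": 0.0,
        },
        seed=17,
    )
    df = syn.simulate_attribution_cohort(cohort=cohort)
    mcmc = SamplerConfig(n_chains=2, n_iter=350, n_warmup=1200,
                         steps_per_iter=4, group_substeps=2, seed=2)
    return fit_attribution(df, mcmc=mcmc, check=False), df


class TestFitting:
    def test_draw_shapes_and_labels(self, quick_attr_fit):
        fit, _ = quick_attr_fit
        assert fit.draws["mu"].shape[2:] == (2, 4)
        assert fit.draws["phi_int"].shape[2:] == (2, 2)
        assert fit.draws["theta"].shape[2:] == (20, 2, 4)
        s = fit.summary()
        assert "mu[pos,internal,1]" in s.index
        assert "phi_int[neg,internal]" in s.index

    def test_all_positive_responses_identify_positive_traits(self):
        cohort = syn.default_attribution_cohort(n_subjects=8, seed=3)
        df = syn.simulate_attribution_cohort(cohort=cohort)
        df["choice_internal"] = 1
        df["choice_global"] = 1
        mcmc = SamplerConfig(n_chains=2, n_iter=150, n_warmup=600,
                             steps_per_iter=2, seed=1)
        fit = fit_attribution(df, mcmc=mcmc, check=False)
        mu = fit.pooled("mu").mean(axis=0)
        assert np.all(mu > 0)

    def test_intervention_summary_covers_all_cells(self, quick_attr_fit):
        fit, _ = quick_attr_fit
        effects = attribution_intervention_summary(fit)
        names = {e.parameter for e in effects}
        assert names == {
            "phi_int[internal,pos]", "phi_int[global,pos]",
            "phi_int[internal,neg]", "phi_int[global,neg]",
        }

    def test_endorsement_summary_transform_oracle(self, quick_attr_fit):
        from scipy.special import expit

        fit, _ = quick_attr_fit
        es = endorsement_summary(fit)
        assert ((es.p_mean > 0) & (es.p_mean < 1)).all()
        # direct transformation of the draws for one cell
        row = es[(es.subject_id == 0) & (es.valence == "pos")
                 & (es.dimension == "internal") & (es.session == 1)]
        draws = expit(fit.pooled("theta")[:, 0, 0, 0])
        assert row["p_mean"].iloc[0] == pytest.approx(draws.mean())
        assert row["p_sd"].iloc[0] == pytest.approx(draws.std(), rel=1e-6)

    def test_valence_separation(self, quick_attr_fit):
        # perturbing only negative-event responses must leave positive-
        # event group means essentially unchanged (they share no traits)
        fit, df = quick_attr_fit
        df2 = df.copy()
        neg = df2.valence == "neg"
        rng = np.random.default_rng(5)
        df2.loc[neg, "choice_internal"] = rng.integers(
            0, 2, size=int(neg.sum())
        )
        mcmc = SamplerConfig(n_chains=2, n_iter=250, n_warmup=900,
                             steps_per_iter=3, seed=6)
        fit_a = fit_attribution(df, mcmc=mcmc, check=False)
        fit_b = fit_attribution(df2, mcmc=mcmc, check=False)
        mu_a = fit_a.pooled("mu")[:, 0, :].mean(axis=0)  # pos valence
        mu_b = fit_b.pooled("mu")[:, 0, :].mean(axis=0)
        se = fit_a.pooled("mu")[:, 0, :].std(axis=0) / np.sqrt(50)
        assert np.all(np.abs(mu_a - mu_b) < 8 * np.maximum(se, 0.05))
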