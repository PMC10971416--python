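"""HTE decomposition arithmetic and repeated-measures interaction power."""

import numpy as np
import pytest
from scipy import stats

from cogmech.hte import (
    PowerSpec,
    change_scores,
    rm_interaction_power,
    required_sample_size,
    sd_individual_response,
)


class TestSdIndividualResponse:
    def test_equal_variances_give_zero_and_class_none(self):
        r = sd_individual_response(0.4, 0.4, 49, 49)
        assert r.SD_IR == 0.0
        assert r.effect_class == "none"
        assert not r.no_heterogeneity

    def test_printed_arithmetic_example(self):
        r = sd_individual_response(0.5, 0.3, 99, 99)
        assert r.SD_IR == pytest.approx(0.4)
        assert r.SD_IRse == pytest.approx(0.03778, abs=5e-5)
        assert r.CI95[0] == pytest.approx(0.326, abs=5e-4)
        assert r.CI95[1] == pytest.approx(0.474, abs=5e-4)
        assert r.effect_class == "moderate"

    def test_variance_identity(self):
        # SD_IR^2 + SD_Con^2 = SD_Act^2 whenever SD_Act >= SD_Con
        for sd_act, sd_con in [(0.5, 0.3), (1.2, 0.7), (0.31, 0.30)]:
            r = sd_individual_response(sd_act, sd_con, 10, 10)
            assert r.SD_IR**2 + sd_con**2 == pytest.approx(sd_act**2)

    def test_negative_difference_clamped_and_flagged(self):
        r = sd_individual_response(0.2, 0.5, 30, 30)
        assert r.SD_IR == 0.0 and r.no_heterogeneity
        signed = sd_individual_response(0.2, 0.5, 30, 30,
                                        allow_negative=True)
        assert signed.SD_IR == pytest.approx(-np.sqrt(0.21))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            sd_individual_response(-0.1, 0.3, 10, 10)

    def test_ci_agrees_with_bootstrap(self):
        # simulate arm change scores whose SDs match the analytic example;
        # a nonparametric bootstrap CI should have similar width
        rng = np.random.default_rng(42)
        n = 500
        act = rng.normal(0, 0.5, n)
        con = rng.normal(0, 0.3, n)
        r = sd_individual_response(
            act.std(ddof=1), con.std(ddof=1), n - 1, n - 1
        )
        boots = []
        for _ in range(500):
            a = rng.choice(act, n)
            c = rng.choice(con, n)
            diff = np.var(a, ddof=1) - np.var(c, ddof=1)
            boots.append(np.sqrt(max(diff, 0.0)))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        analytic_width = r.CI95[1] - r.CI95[0]
        # the analytic SE is a variance-scale approximation: it understates
        # the bootstrap width by the delta-method factor 1/(2*SD_IR), about
        # 25% here, so agreement is asserted at the 30% level
        assert abs((hi - lo) - analytic_width) / analytic_width < 0.3


class TestChangeScores:
    def _toy_fit(self, s1, s2, arms):
        from cogmech.results import PosteriorFit

        n = len(s1)
        subj = np.zeros((1, 1, n, 2, 2))
        subj[0, 0, :, 1, 0] = s1
        subj[0, 0, :, 1, 1] = s2
        return PosteriorFit(
            draws={"subj": subj},
            n_chains=1,
            n_warmup=0,
            model="reward-effort",
            meta={
                "subject_ids": np.arange(n),
                "active": np.asarray(arms),
                "params": ("rewSens", "effSens"),
                "subject_level": ("subj",),
            },
        )

    def test_identical_sessions_give_zero_change(self):
        s1 = np.array([1.0, 2.0, 3.0, 4.0])
        fit = self._toy_fit(s1, s1, [True, True, False, False])
        cs = change_scores(fit, "effSens")
        assert np.allclose(cs["change"], 0.0)

    def test_uniform_one_sd_shift_in_active_arm(self):
        rng = np.random.default_rng(0)
        s1 = rng.normal(0, 1.0, 200)
        arms = np.arange(200) < 100
        s2 = s1 + np.where(arms, np.std(s1, ddof=1), 0.0)
        fit = self._toy_fit(s1, s2, arms)
        cs = change_scores(fit, "effSens")
        assert cs.loc[cs.arm == "active", "change"].mean() == pytest.approx(
            1.0
        )
        assert cs.loc[cs.arm == "control", "change"].mean() == pytest.approx(
            0.0
        )

    def test_hand_computed_four_subject_fixture(self):
        s1 = np.array([1.0, 2.0, 3.0, 4.0])
        s2 = np.array([2.0, 2.0, 2.0, 5.0])
        arms = np.array([True, True, False, False])
        fit = self._toy_fit(s1, s2, arms)
        cs = change_scores(fit, "effSens")
        baseline_sd = np.std(s1, ddof=1)  # ~1.2910
        np.testing.assert_allclose(
            cs["change"], (s2 - s1) / baseline_sd, rtol=1e-12
        )

    def test_single_arm_rejected(self):
        s1 = np.arange(4.0)
        fit = self._toy_fit(s1, s1, [True] * 4)
        with pytest.raises(ValueError):
            change_scores(fit, "effSens")


class TestPower:
    def test_null_effect_power_equals_alpha(self):
        spec = PowerSpec(d=0.0, N=48, rho=0.6, alpha=0.05)
        assert rm_interaction_power(spec) == pytest.approx(0.05)

    def test_published_configurations_reach_95_percent(self):
        assert rm_interaction_power(
            PowerSpec(d=0.48, N=48, m=2, rho=0.6, alpha=0.05)
        ) >= 0.95
        assert rm_interaction_power(
            PowerSpec(d=0.47, N=72, m=2, rho=0.43, alpha=0.05)
        ) >= 0.95

    def test_power_monotone_in_n_d_rho(self):
        base = dict(d=0.4, N=40, m=2, rho=0.5, alpha=0.05)
        p0 = rm_interaction_power(PowerSpec(**base))
        assert rm_interaction_power(PowerSpec(**{**base, "N": 80})) > p0
        assert rm_interaction_power(PowerSpec(**{**base, "d": 0.6})) > p0
        assert rm_interaction_power(PowerSpec(**{**base, "rho": 0.8})) > p0

    def test_required_sample_size_definition(self):
        n = required_sample_size(0.48, 0.95, rho=0.6)
        assert n <= 48
        assert rm_interaction_power(PowerSpec(d=0.48, N=n, rho=0.6)) >= 0.95
        assert rm_interaction_power(
            PowerSpec(d=0.48, N=n - 2, rho=0.6)
        ) < 0.95

    def test_required_n_monotone_in_d(self):
        ns = [required_sample_size(d, 0.9, rho=0.5)
              for d in (0.3, 0.5, 0.8)]
        assert ns == sorted(ns, reverse=True)

    def test_zero_effect_unreachable(self):
        with pytest.raises(ValueError):
            required_sample_size(0.0, 0.95, rho=0.5)

    def test_simulated_rejection_rate_matches_power(self):
        # paired-difference t test equivalent of the two-group two-occasion
        # interaction: simulate change scores and compare rejection rate
        spec = PowerSpec(d=0.3, N=60, m=2, rho=0.5, alpha=0.05)
        power = rm_interaction_power(spec)
        rng = np.random.default_rng(123)
        n_per = spec.N // 2
        # generative mapping implied by the noncentrality convention: the
        # group difference in change scores is d*sqrt(2/(1-rho)) in
        # change-score SD units (two measures per subject)
        delta = spec.d * np.sqrt(2.0 / (1.0 - spec.rho))
        rejections = 0
        n_sim = 4000
        for _ in range(n_sim):
            a = rng.normal(delta, 1.0, n_per)
            c = rng.normal(0.0, 1.0, n_per)
            t = stats.ttest_ind(a, c)
            rejections += t.pvalue < spec.alpha
        rate = rejections / n_sim
        se = np.sqrt(power * (1 - power) / n_sim)
        assert abs(rate - power) < max(2 * se, 0.02)
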