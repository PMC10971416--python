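"""SBC primitives: rank statistic, uniformity diagnostics, self-consistency."""

import numpy as np
import pytest
from scipy import stats

from cogmech.sbc import (
    SBCResult,
    rank_statistic,
    sbc_run,
    uniformity_diagnostics,
)


class TestRankStatistic:
    def test_direct_count(self):
        assert rank_statistic(2.5, [1, 2, 3, 4]) == 2

    def test_extremes(self):
        draws = np.arange(10.0)
        assert rank_statistic(-1.0, draws) == 0
        assert rank_statistic(99.0, draws) == 10

    def test_empty_draws_raise(self):
        with pytest.raises(ValueError):
            rank_statistic(0.0, [])

    def test_tie_randomization_spans_range(self):
        rng = np.random.default_rng(0)
        draws = np.zeros(8)
        ranks = {rank_statistic(0.0, draws, rng) for _ in range(500)}
        assert ranks == set(range(9))

    def test_invariance_under_monotone_transform(self, rng):
        # ranks do not change under a strictly increasing reparameterization
        for _ in range(50):
            draws = rng.lognormal(size=40)
            value = rng.lognormal()
            assert rank_statistic(value, draws) == rank_statistic(
                np.log(value), np.log(draws)
            )


class TestUniformityDiagnostics:
    def test_perfectly_uniform_counts(self):
        D = 99
        ranks = np.repeat(np.arange(10) * 10 + 5, 10)  # 10 per bin
        d = uniformity_diagnostics(ranks, D, n_bins=10)
        assert d["chi2"] == pytest.approx(0.0)
        assert d["p_value"] == pytest.approx(1.0)

    def test_degenerate_ranks_rejected(self):
        d = uniformity_diagnostics(np.full(200, 7), 100, n_bins=10)
        assert d["p_value"] < 1e-10
        assert not d["ecdf_pass"]

    def test_too_many_bins_raise(self):
        with pytest.raises(ValueError):
            uniformity_diagnostics(np.arange(5), 10, n_bins=6)

    def test_pvalues_uniform_under_null(self):
        # meta-calibration: chi-square p-values from uniform ranks are
        # themselves approximately uniform
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(1000):
            ranks = rng.integers(0, 201, size=100)
            ps.append(uniformity_diagnostics(ranks, 200, 10)["p_value"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class _ConjugateAdapter:
    """Analytic normal-normal adapter: the posterior is exact, so SBC must
    pass; with a deliberate shift it must fail."""

    def __init__(self, n_obs=10, n_draws=800, shift=0.0):
        self.n_obs = n_obs
        self.n_draws = n_draws
        self.shift = shift

    def prior_sample(self, rng):
        return {"mu": rng.normal(0.0, 1.0)}

    def simulate(self, truth, rng):
        return rng.normal(truth["mu"], 1.0, size=self.n_obs)

    def fit_draws(self, data, seed):
        rng = np.random.default_rng(seed)
        n = len(data)
        post_var = 1.0 / (1.0 + n)
        post_mean = post_var * np.sum(data) + self.shift
        return {
            "mu": rng.normal(post_mean, np.sqrt(post_var), self.n_draws)
        }, True

    def true_values(self, truth):
        return {"mu": truth["mu"]}


class TestSbcRun:
    def test_exact_posterior_passes_uniformity(self):
        res = sbc_run(_ConjugateAdapter(), n_datasets=200, thinning=1, seed=4)
        d = res.diagnostics(n_bins=10, alpha=0.01)
        assert d.loc["mu", "p_value"] > 0.01
        assert res.n_draws == 800

    def test_shifted_posterior_fails_uniformity(self):
        res = sbc_run(
            _ConjugateAdapter(shift=0.5), n_datasets=200, thinning=1, seed=4
        )
        # +0.5 shift is more than one posterior SD: ranks pile up high
        assert res.diagnostics().loc["mu", "p_value"] < 0.01

    def test_same_seed_identical_result(self):
        a = sbc_run(_ConjugateAdapter(), n_datasets=50, thinning=1, seed=9)
        b = sbc_run(_ConjugateAdapter(), n_datasets=50, thinning=1, seed=9)
        np.testing.assert_array_equal(a.ranks["mu"], b.ranks["mu"])

    def test_thinning_reduces_draw_count(self):
        res = sbc_run(_ConjugateAdapter(), n_datasets=5, thinning=4, seed=1)
        assert res.n_draws == 200

    def test_result_frame_schema(self):
        res = sbc_run(_ConjugateAdapter(), n_datasets=10, thinning=1, seed=2)
        df = res.to_frame()
        assert set(df.columns) == {"dataset_id", "parameter", "rank", "D"}
        assert df["rank"].between(0, res.n_draws).all()


class TestBatchedSbc:
    def test_batched_posterior_matches_standard_fit(self):
        # one replicate of the batched sampler vs the general-purpose
        # engine on the same simulated dataset: group-mean posteriors agree
        import pandas as pd

        from cogmech._batched_sbc import batched_sbc_draws
        from cogmech.reward_effort import PriorConfig, fit_reward_effort
        from cogmech.sampling import SamplerConfig
        from cogmech.synthetic import generate_task_design
        from cogmech._batched_sbc import _BatchRewardEffort

        rng = np.random.default_rng(np.random.SeedSequence(14))
        design = generate_task_design(seed=0)
        model = _BatchRewardEffort(1, 20, design,
                                   PriorConfig.pilot_informed(), rng)
        # export the single dataset as a trial table
        n, t = model.n, model.T
        choice = (model.sign[0] > 0).astype(int)
        rows = []
        for i in range(n):
            for j in range(t):
                rows.append({
                    "subject_id": i,
                    "arm": "active" if model.active[i] else "control",
                    "session": 1 if j < t // 2 else 2,
                    "reward_hi": 3 + model.dr[0, 0, j],
                    "reward_lo": 3,
                    "effort_hi": 0.25 + model.de[0, 0, j],
                    "effort_lo": 0.25,
                    "is_catch": 0,
                    "choice_hi": choice[i, j],
                })
        df = pd.DataFrame(rows)

        fit = fit_reward_effort(
            df, priors=PriorConfig.pilot_informed(),
            mcmc=SamplerConfig(n_chains=2, n_iter=500, n_warmup=1500,
                               steps_per_iter=5, seed=2),
            check=False,
        )
        mu_std = fit.pooled("mu").mean(axis=0).ravel()
        sd_std = fit.pooled("mu").std(axis=0).ravel()

        # the same seed path reproduces the identical dataset inside the
        # batched driver, so the two posteriors target the same data
        names, truths, draws = batched_sbc_draws(
            "reward-effort", n_datasets=1, n_subjects=20, n_draws=300,
            warmup=1500, steps_per_draw=8, seed=14, design=design,
            priors=PriorConfig.pilot_informed(),
        )
        mu_idx = [names.index(f"mu[{i},{j}]") for i in range(2)
                  for j in range(2)]
        mu_batch = draws[0, :, mu_idx].mean(axis=1)
        assert np.all(np.abs(mu_batch - mu_std) < 5 * np.maximum(sd_std,
                                                                 0.05))

    def test_batched_deterministic_and_in_range(self):
        from cogmech.sbc import sbc_run_batched

        a = sbc_run_batched("reward-effort", n_datasets=20, n_draws=20,
                            warmup=150, steps_per_draw=5, seed=11)
        b = sbc_run_batched("reward-effort", n_datasets=20, n_draws=20,
                            warmup=150, steps_per_draw=5, seed=11)
        for k in a.ranks:
            np.testing.assert_array_equal(a.ranks[k], b.ranks[k])
            assert a.ranks[k].min() >= 0 and a.ranks[k].max() <= a.n_draws
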