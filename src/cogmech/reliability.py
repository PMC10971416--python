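"""Test-retest reliability and posterior-predictive fit metrics.

Reliability is estimated the hierarchical way: both sessions are fitted in
one model with separate session group means, subject parameters drawn from a
multivariate normal across time points and a uniform [-1, 1] prior on their
cross-session correlation. The posterior of that correlation (R) is the
reliability estimate, propagating each subject's measurement precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .metrics import FitMetrics, pseudo_r2, rhat  # noqa: F401 (re-export)
from .results import PosteriorFit
from .sampling import SamplerConfig

__all__ = [
    "ReliabilityEstimate",
    "estimate_test_retest",
    "posterior_predictive_accuracy",
    "compute_fit_metrics",
    "pseudo_r2",
    "rhat",
]


@dataclass(frozen=True)
class ReliabilityEstimate:
    parameter: str
    R_mu: float
    ci_low: float
    ci_high: float
    level: float = 0.90

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "R_mu": self.R_mu,
            "q05": self.ci_low,
            "q95": self.ci_high,
        }


def _reliability_from_fit(
    fit: PosteriorFit, params: list[str], level: float
) -> list[ReliabilityEstimate]:
    alpha = (1.0 - level) / 2.0
    out = []
    R = fit.pooled("R")
    labels = fit.labels.get("R", [str(i) for i in range(R.shape[-1])])
    flatR = R.reshape(R.shape[0], -1)
    for k, lab in enumerate(labels):
        if params and lab not in params:
            continue
        draws = flatR[:, k]
        lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
        out.append(
            ReliabilityEstimate(
                parameter=lab,
                R_mu=float(draws.mean()),
                ci_low=float(lo),
                ci_high=float(hi),
                level=level,
            )
        )
    return out


def estimate_test_retest(
    data: pd.DataFrame,
    model: str = "reward-effort",
    mcmc: SamplerConfig | None = None,
    level: float = 0.90,
    check: bool = True,
) -> list[ReliabilityEstimate]:
    """Posterior cross-session correlation (R) per model parameter.

    Fits the two-session hierarchy with the intervention term disabled (any
    arm labels are ignored), so R reflects plain repeat administration.
    """
    sessions = set(data["session"].unique())
    if sessions != {1, 2}:
        raise ValueError(
            "test-retest estimation needs exactly two sessions per subject"
        )
    data = data.drop(columns=["arm"], errors="ignore")
    if model in ("reward-effort", "reward_effort"):
        from .reward_effort import fit_reward_effort

        fit = fit_reward_effort(
            data, mcmc=mcmc, intervention=False, check=check
        )
        wanted = ["rewSens", "effSens"]
    elif model == "attribution":
        from .attribution import fit_attribution

        fit = fit_attribution(data, mcmc=mcmc, intervention=False,
                              check=check)
        wanted = [f"{v},{d}" for v in ("pos", "neg")
                  for d in ("internal", "global")]
    else:
        raise ValueError(f"unknown model {model!r}")
    return _reliability_from_fit(fit, wanted, level)


def _subject_mean_params(fit: PosteriorFit) -> np.ndarray:
    key = "subj" if "subj" in fit.draws else "theta"
    return fit.pooled(key).mean(axis=0)


def posterior_predictive_accuracy(
    fit: PosteriorFit,
    data: pd.DataFrame,
    n_replications: int = 100,
    seed: int = 0,
    use: str = "mean",
) -> dict:
    """Mean per-participant match between replicated and observed choices.

    Replicated choices are drawn stochastically from posterior parameter
    estimates on the observed trial arrays; ``use='mean'`` simulates from
    posterior-mean subject parameters, ``use='draws'`` from a random
    posterior draw per replication. For the attribution task the internal
    and global codes are scored as two separate accuracy streams.
    """
    rng = np.random.default_rng(seed)
    sids = fit.meta["subject_ids"]
    sid_index = {s: i for i, s in enumerate(sids)}
    if use not in ("mean", "draws"):
        raise ValueError("use must be 'mean' or 'draws'")

    if fit.model.startswith("reward-effort") or "subj" in fit.draws:
        df = data[data["is_catch"] == 0] if "is_catch" in data else data
        pooled = fit.pooled("subj")
        mean_params = pooled.mean(axis=0)
        acc = np.zeros(len(sids))
        for sid, grp in df.groupby("subject_id"):
            i = sid_index[sid]
            dr = grp["reward_hi"].to_numpy() - grp["reward_lo"].to_numpy()
            de = grp["effort_hi"].to_numpy() - grp["effort_lo"].to_numpy()
            s2 = (grp["session"].to_numpy() == 2).astype(int)
            y = grp["choice_hi"].to_numpy()
            match = 0.0
            for r in range(n_replications):
                p = (
                    mean_params[i]
                    if use == "mean"
                    else pooled[rng.integers(pooled.shape[0]), i]
                )
                logit = p[0, s2] * dr - p[1, s2] * de
                rep = rng.random(len(y)) < expit(logit)
                match += np.mean(rep == y)
            acc[i] = match / n_replications
        return {"ppa_mean": float(acc.mean()), "ppa_sd": float(acc.std(ddof=1)),
                "per_subject": acc}

    # attribution: two streams
    pooled = fit.pooled("theta")
    mean_theta = pooled.mean(axis=0)  # (n, valence, 4 cells)
    acc_int = np.zeros(len(sids))
    acc_glob = np.zeros(len(sids))
    for sid, grp in data.groupby("subject_id"):
        i = sid_index[sid]
        v = (grp["valence"] == "neg").to_numpy().astype(int)
        s = grp["session"].to_numpy() - 1
        yi = grp["choice_internal"].to_numpy()
        yg = grp["choice_global"].to_numpy()
        mi = mg = 0.0
        for r in range(n_replications):
            th = (
                mean_theta[i]
                if use == "mean"
                else pooled[rng.integers(pooled.shape[0]), i]
            )
            p_int = expit(th[v, s * 2 + 0])
            p_glob = expit(th[v, s * 2 + 1])
            mi += np.mean((rng.random(len(yi)) < p_int) == yi)
            mg += np.mean((rng.random(len(yg)) < p_glob) == yg)
        acc_int[i] = mi / n_replications
        acc_glob[i] = mg / n_replications
    return {
        "ppa_internal_mean": float(acc_int.mean()),
        "ppa_internal_sd": float(acc_int.std(ddof=1)),
        "ppa_global_mean": float(acc_glob.mean()),
        "ppa_global_sd": float(acc_glob.std(ddof=1)),
        "per_subject_internal": acc_int,
        "per_subject_global": acc_glob,
    }


def compute_fit_metrics(
    fit: PosteriorFit,
    data: pd.DataFrame,
    n_replications: int = 100,
    seed: int = 0,
) -> FitMetrics:
    """Posterior predictive accuracy plus pseudo-r2 at posterior-mean
    subject parameters (the default; a draws-averaged PPA variant is
    available through :func:`posterior_predictive_accuracy`)."""
    ppa = posterior_predictive_accuracy(
        fit, data, n_replications=n_replications, seed=seed
    )
    if "subj" in fit.draws:
        df = data[data["is_catch"] == 0] if "is_catch" in data else data
        mean_params = fit.pooled("subj").mean(axis=0)
        sids = fit.meta["subject_ids"]
        sid_index = {s: i for i, s in enumerate(sids)}
        L = 0.0
        t = 0
        for sid, grp in df.groupby("subject_id"):
            i = sid_index[sid]
            dr = grp["reward_hi"].to_numpy() - grp["reward_lo"].to_numpy()
            de = grp["effort_hi"].to_numpy() - grp["effort_lo"].to_numpy()
            s2 = (grp["session"].to_numpy() == 2).astype(int)
            sign = 2.0 * grp["choice_hi"].to_numpy() - 1.0
            logit = mean_params[i, 0, s2] * dr - mean_params[i, 1, s2] * de
            L += float(-np.logaddexp(0.0, -sign * logit).sum())
            t += len(grp)
        ppa_mean, ppa_sd = ppa["ppa_mean"], ppa["ppa_sd"]
    else:
        mean_theta = fit.pooled("theta").mean(axis=0)
        sids = fit.meta["subject_ids"]
        sid_index = {s: i for i, s in enumerate(sids)}
        L = 0.0
        t = 0
        for sid, grp in data.groupby("subject_id"):
            i = sid_index[sid]
            v = (grp["valence"] == "neg").to_numpy().astype(int)
            s = grp["session"].to_numpy() - 1
            for dim, col in ((0, "choice_internal"), (1, "choice_global")):
                sign = 2.0 * grp[col].to_numpy() - 1.0
                logit = mean_theta[i, v, s * 2 + dim]
                L += float(-np.logaddexp(0.0, -sign * logit).sum())
                t += len(grp)
        ppa_mean = 0.5 * (ppa["ppa_internal_mean"] + ppa["ppa_global_mean"])
        ppa_sd = 0.5 * (ppa["ppa_internal_sd"] + ppa["ppa_global_sd"])
    C = t * np.log(0.5)
    return FitMetrics(
        ppa_mean=ppa_mean,
        ppa_sd=ppa_sd,
        pseudo_r2=pseudo_r2(L, t, 2),
        L=L,
        C=float(C),
    )
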