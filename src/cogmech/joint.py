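"""Graded-response IRT models and joint symptom-behaviour estimation.

Ordinal symptom items (synthetic stand-ins for AMI, PHQ9 and DAS items) are
modelled with unidimensional graded response models (GRMs): the probability
of responding in category k or above is logistic in ``a_j * theta - kappa_jk``
with positive item discriminations ``a_j`` and ordered thresholds. Latent
traits are identified on a standard-normal scale.

The joint model embeds the GRM(s) inside the behavioural task hierarchy:
each subject's trait shifts the target behavioural parameter at baseline
(``beta_BASE * theta``) and, for active-arm subjects, moderates the
intervention effect at session 2 (``beta_INT * theta``). Coefficients with a
90% credible interval excluding zero are read as evidence of moderation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .results import PosteriorFit, effect_from_draws
from .reward_effort import PriorConfig, RewardEffortTarget, PARAMS
from .sampling import SamplerConfig, run_mcmc
from .synthetic import ItemBank, grm_category_probabilities

__all__ = [
    "fit_grm",
    "fit_joint",
    "standardized_beta",
    "joint_coefficient_summary",
]


# ---------------------------------------------------------------------------
# GRM internals
# ---------------------------------------------------------------------------


class _GrmBlock:
    """Vectorized GRM likelihood for one trait's item set.

    Item parameters are packed per item as (log a, kappa_1, log diffs);
    responses are stored as a dense (n_subjects, n_items) matrix.
    """

    def __init__(self, item_df: pd.DataFrame, subject_ids: np.ndarray):
        self.item_ids = list(dict.fromkeys(item_df["item_id"]))
        j = len(self.item_ids)
        n = len(subject_ids)
        sid_index = {s: i for i, s in enumerate(subject_ids)}
        wide = item_df.pivot_table(
            index="subject_id", columns="item_id", values="response",
            aggfunc="first",
        )
        missing = set(subject_ids) - set(wide.index)
        if missing:
            raise KeyError(
                f"item responses missing for subjects {sorted(missing)[:5]}"
            )
        wide = wide.loc[subject_ids, self.item_ids]
        self.resp = wide.to_numpy().astype(int)  # (n, j)
        self.n_cat = self.resp.max(axis=0) + 1
        for jj, item in enumerate(self.item_ids):
            if len(np.unique(self.resp[:, jj])) < 2:
                raise ValueError(
                    f"item {item} shows fewer than two observed categories"
                )
        self.k_max = int(self.n_cat.max())
        self.n_params_per_item = 1 + (self.n_cat - 1)  # log a + thresholds
        self.dim = int(self.n_params_per_item.sum())
        # slices into the packed item-parameter vector
        offs = np.concatenate([[0], np.cumsum(self.n_params_per_item)])
        self.offsets = offs

    def unpack(self, vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (a, thresholds padded with +inf), shapes (j,), (j, k_max-1)."""
        j = len(self.item_ids)
        a = np.empty(j)
        kappa = np.full((j, self.k_max - 1), np.inf)
        for jj in range(j):
            seg = vec[self.offsets[jj] : self.offsets[jj + 1]]
            a[jj] = np.exp(seg[0])
            k = self.n_cat[jj] - 1
            kappa[jj, :k] = seg[1] + np.concatenate(
                [[0.0], np.cumsum(np.exp(seg[2 : 1 + k]))]
            )
        return a, kappa

    def per_subject_loglik(self, vec: np.ndarray, theta: np.ndarray
                           ) -> np.ndarray:
        from scipy.special import expit

        a, kappa = self.unpack(vec)
        # cumulative curves bracketing each observed response
        j_idx = np.arange(len(self.item_ids))
        x = a[None, :] * theta[:, None]
        pad = np.concatenate(
            [np.full((len(self.item_ids), 1), -np.inf), kappa,
             np.full((len(self.item_ids), 1), np.inf)],
            axis=1,
        )
        lo = pad[j_idx[None, :], self.resp]
        hi = pad[j_idx[None, :], self.resp + 1]
        p = expit(x - lo) - expit(x - hi)
        return np.log(np.maximum(p, 1e-300)).sum(axis=1)

    def log_prior(self, vec: np.ndarray, a_scale: float = 0.5,
                  kappa_scale: float = 2.0) -> float:
        """log a ~ N(0, a_scale); each threshold ~ N(0, kappa_scale) on the
        ordered region, with the log-difference Jacobian."""
        lp = 0.0
        for jj in range(len(self.item_ids)):
            seg = vec[self.offsets[jj] : self.offsets[jj + 1]]
            lp += -0.5 * (seg[0] / a_scale) ** 2
            k = self.n_cat[jj] - 1
            kappa = seg[1] + np.concatenate(
                [[0.0], np.cumsum(np.exp(seg[2 : 1 + k]))]
            )
            lp += np.sum(-0.5 * (kappa / kappa_scale) ** 2)
            lp += np.sum(seg[2 : 1 + k])  # Jacobian of the log-diffs
        return float(lp)

    def init_vec(self, rng) -> np.ndarray:
        vec = np.empty(self.dim)
        for jj in range(len(self.item_ids)):
            seg = slice(self.offsets[jj], self.offsets[jj + 1])
            k = self.n_cat[jj] - 1
            vals = np.empty(1 + k)
            vals[0] = 0.2 * rng.standard_normal()
            vals[1] = -1.0 + 0.2 * rng.standard_normal()
            vals[2:] = np.log(2.0 / max(k - 1, 1)) + 0.1 * rng.standard_normal(
                max(k - 1, 0)
            )
            vec[seg] = vals
        return vec

    def item_blocks(self, offset: int) -> list[tuple[str, np.ndarray]]:
        return [
            (
                f"item_{self.item_ids[jj]}",
                np.arange(self.offsets[jj] + offset,
                          self.offsets[jj + 1] + offset),
            )
            for jj in range(len(self.item_ids))
        ]


class GrmTarget:
    """Stand-alone unidimensional GRM for one trait."""

    def __init__(self, item_df: pd.DataFrame, trait: str):
        sub = item_df[item_df["trait"] == trait]
        if sub["item_id"].nunique() < 2:
            raise ValueError("need at least two items for the trait")
        self.subject_ids = np.sort(sub["subject_id"].unique())
        self.n_subjects = len(self.subject_ids)
        self.block = _GrmBlock(sub, self.subject_ids)
        self.group_dim = self.block.dim
        self.group_blocks = self.block.item_blocks(0)
        self.z_blocks = [("theta", 1)]

    def per_subject_loglik(self, group, z):
        return self.block.per_subject_loglik(group, z["theta"][:, 0])

    def group_log_prior(self, group):
        return self.block.log_prior(group)

    def init_group(self, rng):
        return self.block.init_vec(rng)

    def init_z(self, rng):
        return {"theta": 0.3 * rng.standard_normal((self.n_subjects, 1))}

    def record(self, group, z, record_subjects):
        a, kappa = self.block.unpack(group)
        out = {"a": a, "kappa": kappa.copy()}
        if record_subjects:
            out["theta"] = z["theta"][:, 0].copy()
        return out

    @property
    def labels(self):
        j = self.block
        return {
            "a": list(j.item_ids),
            "kappa": [
                f"{item},{k + 1}"
                for item in j.item_ids
                for k in range(j.k_max - 1)
            ],
        }


def fit_grm(
    data: pd.DataFrame,
    trait: str,
    mcmc: SamplerConfig | None = None,
    check: bool = True,
) -> PosteriorFit:
    """Fit a unidimensional graded response model for one trait label.

    Identification: subject traits have a standard-normal population prior
    and discriminations are positive (log-scale sampling).
    """
    mcmc = mcmc or SamplerConfig.test_profile()
    target = GrmTarget(data, trait)
    draws, info = run_mcmc(target, mcmc)
    fit = PosteriorFit(
        draws=draws,
        n_chains=mcmc.n_chains,
        n_warmup=mcmc.n_warmup,
        model=f"grm-{trait}",
        labels=target.labels,
        meta={
            "subject_ids": target.subject_ids,
            "subject_level": ("theta",),
            "trait": trait,
            "target": target,
        },
        info=info,
    )
    if check:
        fit.check_convergence()
    return fit


# ---------------------------------------------------------------------------
# Joint model
# ---------------------------------------------------------------------------


class JointTarget(RewardEffortTarget):
    """Reward-effort hierarchy with trait moderation of one parameter.

    Extends the behavioural group vector with per-trait GRM item parameters
    and (beta_BASE, beta_INT) weights. Subject traits are extra latent
    blocks with standard-normal priors, informing both the GRM likelihood
    and — through the beta weights — the behavioural likelihood.
    """

    def __init__(
        self,
        task_data: pd.DataFrame,
        item_data: pd.DataFrame,
        target: str = "effSens",
        traits: tuple[str, ...] = ("A",),
        priors: PriorConfig | None = None,
        beta_scale: float = 1.0,
        fixed_traits: dict[str, np.ndarray] | None = None,
    ):
        super().__init__(task_data, priors=priors, intervention=True)
        if target not in PARAMS:
            raise ValueError(f"unknown target parameter {target!r}")
        self.target_param = PARAMS.index(target)
        self.trait_labels = tuple(traits)
        self.beta_scale = beta_scale
        self.fixed_traits = fixed_traits or {}

        overlap = set(self.subject_ids) & set(item_data["subject_id"])
        if len(overlap) < self.n_subjects:
            raise KeyError(
                "item responses must cover every subject in the task data"
            )

        self.grm_blocks: dict[str, _GrmBlock] = {}
        offset = self.behav_dim
        extra_blocks: list[tuple[str, np.ndarray]] = []
        for tr in self.trait_labels:
            blk = _GrmBlock(
                item_data[item_data["trait"] == tr], self.subject_ids
            )
            self.grm_blocks[tr] = blk
            blk.offset = offset
            extra_blocks.extend(blk.item_blocks(offset))
            offset += blk.dim
        self.beta_offset = offset
        n_tr = len(self.trait_labels)
        self.group_dim = offset + 2 * n_tr  # beta_base, beta_int per trait
        beta_idx = np.arange(self.beta_offset, self.group_dim)
        # betas ride in the location block so they co-adapt with phi_int
        loc_name, loc_idx = self.group_blocks[0]
        self.group_blocks = [
            (loc_name, np.concatenate([loc_idx, beta_idx])),
            self.group_blocks[1],
            *extra_blocks,
        ]
        if not self.fixed_traits:
            self.z_blocks = self.z_blocks + [
                (f"theta_{tr}", 1) for tr in self.trait_labels
            ]

        # likelihood components: behavioural data plus one GRM per trait
        self.components = ("behav",) + tuple(
            f"grm_{tr}" for tr in self.trait_labels
        )
        self.block_components = {
            "subj": ("behav",),
            "group_loc": ("behav",),
            "group_scale": ("behav",),
        }
        for tr in self.trait_labels:
            # the trait informs its GRM and, through the betas, behaviour
            self.block_components[f"theta_{tr}"] = ("behav", f"grm_{tr}")
            for name, _ in self.grm_blocks[tr].item_blocks(0):
                self.block_components[name] = (f"grm_{tr}",)

    # -- helpers -----------------------------------------------------------
    def _theta(self, z, trait):
        if trait in self.fixed_traits:
            return self.fixed_traits[trait]
        return z[f"theta_{trait}"][:, 0]

    def betas(self, group) -> dict[str, tuple[float, float]]:
        out = {}
        for i, tr in enumerate(self.trait_labels):
            b = group[self.beta_offset + 2 * i : self.beta_offset + 2 * i + 2]
            out[tr] = (float(b[0]), float(b[1]))
        return out

    def subject_params(self, group, z):
        p = super().subject_params(group[: self.behav_dim], z)
        for i, tr in enumerate(self.trait_labels):
            theta = self._theta(z, tr)
            b_base = group[self.beta_offset + 2 * i]
            b_int = group[self.beta_offset + 2 * i + 1]
            p[:, self.target_param, 0] += b_base * theta
            p[self.active, self.target_param, 1] += (
                b_int * theta[self.active]
            )
        return p

    # -- GibbsTarget interface --------------------------------------------
    def loglik_component(self, group, z, comp):
        if comp == "behav":
            return super().per_subject_loglik(group, z)
        tr = comp.removeprefix("grm_")
        blk = self.grm_blocks[tr]
        vec = group[blk.offset : blk.offset + blk.dim]
        return blk.per_subject_loglik(vec, self._theta(z, tr))

    def per_subject_loglik(self, group, z):
        ll = self.loglik_component(group, z, "behav")
        for tr in self.trait_labels:
            ll = ll + self.loglik_component(group, z, f"grm_{tr}")
        return ll

    def group_log_prior(self, group):
        lp = super().group_log_prior(group[: self.behav_dim])
        for tr in self.trait_labels:
            blk = self.grm_blocks[tr]
            lp += blk.log_prior(group[blk.offset : blk.offset + blk.dim])
        betas = group[self.beta_offset :]
        lp += float(np.sum(-0.5 * (betas / self.beta_scale) ** 2))
        return lp

    def init_group(self, rng):
        g = np.empty(self.group_dim)
        g[: self.behav_dim] = super().init_group(rng)
        for tr in self.trait_labels:
            blk = self.grm_blocks[tr]
            g[blk.offset : blk.offset + blk.dim] = blk.init_vec(rng)
        g[self.beta_offset :] = 0.1 * rng.standard_normal(
            2 * len(self.trait_labels)
        )
        return g

    def init_z(self, rng):
        z = super().init_z(rng)
        if not self.fixed_traits:
            for tr in self.trait_labels:
                z[f"theta_{tr}"] = 0.3 * rng.standard_normal(
                    (self.n_subjects, 1)
                )
        return z

    def record(self, group, z, record_subjects):
        out = super().record(group[: self.behav_dim], z, False)
        names = []
        for i, tr in enumerate(self.trait_labels):
            names.append(tr)
        out["beta_base"] = np.array(
            [group[self.beta_offset + 2 * i] for i in range(len(names))]
        )
        out["beta_int"] = np.array(
            [group[self.beta_offset + 2 * i + 1] for i in range(len(names))]
        )
        if record_subjects:
            out["subj"] = self.subject_params(group, z)
            for tr in self.trait_labels:
                out[f"theta_{tr}"] = self._theta(z, tr).copy()
        return out

    @property
    def joint_labels(self):
        lab = dict(RewardEffortTarget.labels)
        lab["beta_base"] = list(self.trait_labels)
        lab["beta_int"] = list(self.trait_labels)
        return lab


def fit_joint(
    task_data: pd.DataFrame,
    item_data: pd.DataFrame,
    target: str = "effSens",
    traits: tuple[str, ...] = ("A",),
    mcmc: SamplerConfig | None = None,
    priors: PriorConfig | None = None,
    two_step: bool = False,
    check: bool = True,
) -> PosteriorFit:
    """Jointly fit the behavioural hierarchy, the trait GRM(s) and the
    moderation weights beta_BASE / beta_INT for the target parameter.

    ``two_step=True`` is a diagnostic mode: each trait GRM is fitted first,
    posterior-mean traits (standardized) are then plugged into the
    behavioural model as fixed covariates.
    """
    mcmc = mcmc or SamplerConfig.test_profile()
    fixed = None
    if two_step:
        fixed = {}
        for tr in traits:
            gfit = fit_grm(
                item_data, tr, mcmc=mcmc.with_seed(mcmc.seed + 1000),
                check=False,
            )
            th = gfit.pooled("theta").mean(axis=0)
            fixed[tr] = (th - th.mean()) / th.std(ddof=1)
    model = JointTarget(
        task_data,
        item_data,
        target=target,
        traits=traits,
        priors=priors,
        fixed_traits=fixed,
    )
    draws, info = run_mcmc(model, mcmc)
    fit = PosteriorFit(
        draws=draws,
        n_chains=mcmc.n_chains,
        n_warmup=mcmc.n_warmup,
        model=f"joint-{'+'.join(traits)}-{target}",
        labels=model.joint_labels,
        meta={
            "subject_ids": model.subject_ids,
            "active": model.active,
            "params": PARAMS,
            "target_param": target,
            "traits": traits,
            "subject_level": ("subj",)
            + tuple(f"theta_{tr}" for tr in traits),
            "target": model,
        },
        info=info,
    )
    if check:
        fit.check_convergence()
    return fit


def joint_coefficient_summary(fit: PosteriorFit, level: float = 0.90):
    """Raw beta_BASE / beta_INT posterior summaries with the credible-
    interval zero-exclusion rule."""
    traits = fit.meta["traits"]
    out = []
    for i, tr in enumerate(traits):
        for name in ("beta_base", "beta_int"):
            out.append(
                effect_from_draws(
                    f"{name}[{tr}]", fit.pooled(name)[:, i], level
                )
            )
    return out


def standardized_beta(
    fit: PosteriorFit,
    predictor_sd: float,
    outcome_sd: float,
    name: str = "beta_int",
    trait: str | None = None,
    level: float = 0.90,
):
    """Scale a beta coefficient by the predictor/outcome SD ratio.

    Multiplying every draw by ``predictor_sd / outcome_sd`` expresses the
    weight per SD of trait in SD units of the behavioural outcome; interval
    endpoints scale by the same ratio.
    """
    if predictor_sd <= 0 or outcome_sd <= 0:
        raise ValueError("SDs must be positive")
    traits = list(fit.meta["traits"])
    idx = traits.index(trait) if trait is not None else 0
    draws = fit.pooled(name)[:, idx] * (predictor_sd / outcome_sd)
    return effect_from_draws(
        f"{name}[{traits[idx]}]|standardized", draws, level
    )
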