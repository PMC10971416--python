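"""Hierarchical latent-trait model of internal/global causal attributions.

Each trial's chosen explanation is coded along two dimensions — internal
(versus external) and global (versus specific) — giving two Bernoulli
observations per scenario. A participant's tendency on each dimension is an
unbounded latent trait mapped to an endorsement probability through the
logistic link; separate traits are estimated for positive and negative
events. Within each valence the four traits (two dimensions x two sessions)
follow a multivariate normal with free covariance (half-normal scales,
LKJ(1) correlation), and allocation to the active intervention shifts
session-2 traits by a group-level effect per dimension and valence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _mvn
from .results import EffectSummary, PosteriorFit, effect_from_draws
from .sampling import SamplerConfig, run_mcmc

__all__ = [
    "attribution_probability",
    "attribution_loglik",
    "AttributionPriorConfig",
    "fit_attribution",
    "attribution_intervention_summary",
    "endorsement_summary",
]

VALENCES = ("pos", "neg")
DIMS = ("internal", "global")
# within one valence: (internal s1, global s1, internal s2, global s2)
CELL_LABELS = [
    f"{d},{s}" for s in (1, 2) for d in DIMS
]


def attribution_probability(theta):
    """Probability of endorsing an attribution given its latent trait."""
    return expit(np.asarray(theta, dtype=float))


def attribution_loglik(traits: pd.DataFrame, data: pd.DataFrame) -> float:
    """Summed Bernoulli log likelihood over both coded dimensions.

    ``traits`` needs columns subject_id, session, valence, theta_internal,
    theta_global with one row for every cell appearing in ``data``.
    """
    keyed = traits.set_index(["subject_id", "session", "valence"])
    total = 0.0
    for (sid, sess, val), grp in data.groupby(
        ["subject_id", "session", "valence"]
    ):
        try:
            row = keyed.loc[(sid, sess, val)]
        except KeyError as e:
            raise KeyError(
                f"no traits for subject {sid} session {sess} valence {val}"
            ) from e
        for dim, col in (("theta_internal", "choice_internal"),
                         ("theta_global", "choice_global")):
            y = grp[col].to_numpy()
            sign = 2.0 * y - 1.0
            total += -np.logaddexp(0.0, -sign * float(row[dim])).sum()
    return float(total)


@dataclass(frozen=True)
class AttributionPriorConfig:
    """Priors for the attribution hierarchy: trait group means normal(0, 2),
    per-dimension half-normal(1) scales, LKJ(1) correlation across the four
    within-valence cells, standard-normal intervention effects."""

    mu_scale: float = 2.0
    mu_loc: tuple[float, ...] = (0.0,) * 8
    sd_scale: float = 1.0
    phi_scale: float = 1.0
    lkj_eta: float = 1.0

    @classmethod
    def pilot_informed(cls) -> "AttributionPriorConfig":
        """Narrower priors anchored at the pilot endorsement regime, for
        calibration (SBC) runs."""
        return cls(
            mu_scale=0.5,
            mu_loc=(0.8, 0.4, 0.8, 0.4, -0.2, -0.2, -0.2, -0.2),
            sd_scale=0.4,
            phi_scale=0.5,
        )


# group vector layout, per valence v in (pos, neg), base = v * 16:
#   [base + 0:4]   mu        (int s1, glob s1, int s2, glob s2)
#   [base + 4:8]   log sd
#   [base + 8:14]  atanh canonical partials of the 4x4 correlation
#   [base + 14:16] phi_int   (internal, global)
_V_STRIDE = 16


class AttributionTarget:
    """Blocked-Gibbs target for the attribution latent-trait hierarchy."""

    def __init__(
        self,
        data: pd.DataFrame,
        priors: AttributionPriorConfig | None = None,
        intervention: bool = True,
    ):
        self.priors = priors or AttributionPriorConfig()
        self.intervention = intervention
        self.subject_ids = np.sort(data["subject_id"].unique())
        n = self.n_subjects = len(self.subject_ids)
        sid_index = {s: i for i, s in enumerate(self.subject_ids)}
        if set(data["session"].unique()) != {1, 2}:
            raise ValueError("both sessions are required for every fit")
        if "arm" in data:
            arm = data.groupby("subject_id")["arm"].first()
            self.active = np.array(
                [arm[s] == "active" for s in self.subject_ids]
            )
        else:
            self.active = np.zeros(n, dtype=bool)
        if intervention and self.active.sum() < 2:
            raise ValueError("need >= 2 subjects per arm to fit phi_INT")

        # flatten to one row per (trial x dimension), split by valence so
        # single-valence updates re-evaluate only their own component;
        # within a valence the cell order is (int s1, glob s1, int s2,
        # glob s2) and the cell index is s*2 + dim
        per_val: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {
            "pos": {}, "neg": {}
        }
        for sid, grp in data.groupby("subject_id"):
            i = sid_index[sid]
            for val in VALENCES:
                sub = grp[grp["valence"] == val]
                s = sub["session"].to_numpy() - 1
                yi = sub["choice_internal"].to_numpy()
                yg = sub["choice_global"].to_numpy()
                cells = np.concatenate([s * 2, s * 2 + 1])
                signs = np.concatenate([2.0 * yi - 1.0, 2.0 * yg - 1.0])
                per_val[val][i] = (cells, signs)
        self.cell_v: dict[str, np.ndarray] = {}
        self.sign_v: dict[str, np.ndarray] = {}
        for val in VALENCES:
            t_max = max(len(c) for c, _ in per_val[val].values())
            cell = np.zeros((n, t_max), dtype=np.int64)
            sign = np.zeros((n, t_max))
            for i, (c, sg) in per_val[val].items():
                cell[i, : len(c)] = c
                sign[i, : len(c)] = sg
            self.cell_v[val] = cell
            self.sign_v[val] = sign

        self.group_dim = 2 * _V_STRIDE
        blocks = []
        for vi, v in enumerate(VALENCES):
            base = vi * _V_STRIDE
            loc = list(range(base, base + 4))
            if intervention:
                loc += [base + 14, base + 15]
            blocks.append((f"loc_{v}", np.array(loc)))
            blocks.append((f"scale_{v}", np.arange(base + 4, base + 14)))
        self.group_blocks = blocks
        self.z_blocks = [("z_pos", 4), ("z_neg", 4)]
        self._rows = np.arange(n)[:, None]
        self._chol_cache: list[dict] = [{}, {}]
        self.components = VALENCES
        self.block_components = {
            "z_pos": ("pos",), "z_neg": ("neg",),
            "loc_pos": ("pos",), "scale_pos": ("pos",),
            "loc_neg": ("neg",), "scale_neg": ("neg",),
        }

        from .sampling import RecenterMove

        self.recenter_moves = []
        for vi, v in enumerate(VALENCES):
            base = vi * _V_STRIDE
            loc = list(range(base, base + 4))
            if intervention:
                loc += [base + 14, base + 15]
            self.recenter_moves.append(
                RecenterMove(
                    f"recenter_loc_{v}", np.array(loc),
                    lambda go, gn, z, vi=vi: self._recenter_loc(go, gn, z, vi),
                )
            )
            self.recenter_moves.append(
                RecenterMove(
                    f"recenter_scale_{v}", np.arange(base + 4, base + 14),
                    lambda go, gn, z, vi=vi: self._recenter_scale(
                        go, gn, z, vi
                    ),
                )
            )

    # -- centered (recentering) moves -------------------------------------
    def _chol(self, group, vi):
        # the correlation block changes in only 2 of ~10 update types per
        # sweep; caching by value avoids rebuilding the vine + Cholesky
        base = vi * _V_STRIDE
        c = group[base + 8 : base + 14]
        key = c.tobytes()
        cache = self._chol_cache[vi]
        hit = cache.get(key)
        if hit is None:
            if len(cache) > 64:
                cache.clear()
            L = _mvn.corr_cholesky(_mvn.unconstrained_to_corr(c, 4))
            hit = (L, np.linalg.inv(L))
            cache[key] = hit
        return hit

    def _offsets(self, group, z, vi):
        base = vi * _V_STRIDE
        sd = np.exp(group[base + 4 : base + 8])
        L, _ = self._chol(group, vi)
        zv = z["z_pos" if vi == 0 else "z_neg"]
        return (zv @ L.T) * sd

    def _z_from_offsets(self, group, o, vi):
        base = vi * _V_STRIDE
        sd = np.exp(group[base + 4 : base + 8])
        _, Linv = self._chol(group, vi)
        return (o / sd) @ Linv.T

    def _shift(self, group, vi):
        base = vi * _V_STRIDE
        shift = np.broadcast_to(
            group[base : base + 4], (self.n_subjects, 4)
        ).copy()
        if self.intervention:
            shift[self.active, 2] += group[base + 14]
            shift[self.active, 3] += group[base + 15]
        return shift

    def _logdet_scale(self, group, vi):
        base = vi * _V_STRIDE
        L, _ = self._chol(group, vi)
        return float(
            np.sum(group[base + 4 : base + 8])
            + np.sum(np.log(np.maximum(np.diag(L), 1e-150)))
        )

    def _recenter_loc(self, group_old, group_new, z, vi):
        key = "z_pos" if vi == 0 else "z_neg"
        o = self._offsets(group_old, z, vi)
        o_new = o + self._shift(group_old, vi) - self._shift(group_new, vi)
        return {key: self._z_from_offsets(group_new, o_new, vi)}, 0.0

    def _recenter_scale(self, group_old, group_new, z, vi):
        key = "z_pos" if vi == 0 else "z_neg"
        o = self._offsets(group_old, z, vi)
        log_jac = self.n_subjects * (
            self._logdet_scale(group_old, vi)
            - self._logdet_scale(group_new, vi)
        )
        return {key: self._z_from_offsets(group_new, o, vi)}, log_jac

    # -- parameter construction -------------------------------------------
    def traits(self, group, z) -> np.ndarray:
        """Latent traits, shape (n, 2 valences, 4 cells)."""
        out = np.empty((self.n_subjects, 2, 4))
        for vi in range(2):
            out[:, vi, :] = self._traits_valence(group, z, vi)
        return out

    def theta_flat(self, group, z) -> np.ndarray:
        """(n, 8) trait table: valence-major, cell order as in CELL_LABELS."""
        return self.traits(group, z).reshape(self.n_subjects, 8)

    def _traits_valence(self, group, z, vi) -> np.ndarray:
        """(n, 4) latent traits for one valence."""
        base = vi * _V_STRIDE
        mu = group[base : base + 4]
        sd = np.exp(group[base + 4 : base + 8])
        L, _ = self._chol(group, vi)
        zv = z["z_pos" if vi == 0 else "z_neg"]
        out = mu + (zv @ L.T) * sd
        if self.intervention:
            out[self.active, 2] += group[base + 14]
            out[self.active, 3] += group[base + 15]
        return out

    # -- GibbsTarget interface --------------------------------------------
    def loglik_component(self, group, z, comp: str) -> np.ndarray:
        from ._kernels import bernoulli_row_loglik

        vi = VALENCES.index(comp)
        th = self._traits_valence(group, z, vi)
        logit = th[self._rows, self.cell_v[comp]]
        return bernoulli_row_loglik(logit, self.sign_v[comp])

    def per_subject_loglik(self, group, z) -> np.ndarray:
        return self.loglik_component(group, z, "pos") + self.loglik_component(
            group, z, "neg"
        )

    def group_log_prior(self, group) -> float:
        pr = self.priors
        if not hasattr(self, "_prior_cache"):
            self._prior_cache = (
                np.asarray(pr.mu_loc, dtype=float).reshape(2, 4),
                _mvn.vine_beta_params(4, pr.lkj_eta),
            )
        mu_loc, vine_b = self._prior_cache
        lp = 0.0
        for vi in range(2):
            base = vi * _V_STRIDE
            mu = group[base : base + 4]
            u = group[base + 4 : base + 8]
            c = group[base + 8 : base + 14]
            r = (mu - mu_loc[vi]) / pr.mu_scale
            lp -= 0.5 * float(r @ r)
            sd = np.exp(u)
            lp += float(u.sum()) - 0.5 * float(sd @ sd) / pr.sd_scale**2
            log1m_p2 = np.log(4.0) - 2.0 * np.logaddexp(c, -c)
            lp += float(vine_b @ log1m_p2)
            if self.intervention:
                phi = group[base + 14 : base + 16]
                lp -= 0.5 * float(phi @ phi) / pr.phi_scale**2
        return lp

    def init_group(self, rng) -> np.ndarray:
        g = np.zeros(self.group_dim)
        mu_loc = np.asarray(self.priors.mu_loc).reshape(2, 4)
        for vi in range(2):
            base = vi * _V_STRIDE
            g[base : base + 4] = mu_loc[vi] + 0.3 * rng.standard_normal(4)
            g[base + 4 : base + 8] = np.log(0.8) + 0.2 * rng.standard_normal(4)
            g[base + 8 : base + 14] = 0.1 * rng.standard_normal(6)
            if self.intervention:
                g[base + 14 : base + 16] = 0.1 * rng.standard_normal(2)
        return g

    def init_z(self, rng) -> dict[str, np.ndarray]:
        return {
            "z_pos": 0.3 * rng.standard_normal((self.n_subjects, 4)),
            "z_neg": 0.3 * rng.standard_normal((self.n_subjects, 4)),
        }

    def sample_prior(self, rng) -> tuple[np.ndarray, dict[str, np.ndarray]]:
        pr = self.priors
        g = np.empty(self.group_dim)
        mu_loc = np.asarray(pr.mu_loc).reshape(2, 4)
        for vi in range(2):
            base = vi * _V_STRIDE
            g[base : base + 4] = rng.normal(mu_loc[vi], pr.mu_scale)
            g[base + 4 : base + 8] = np.log(
                np.abs(rng.normal(0.0, pr.sd_scale, 4)) + 1e-8
            )
            g[base + 8 : base + 14] = _mvn.sample_corr_unconstrained(
                rng, 4, pr.lkj_eta
            )
            if self.intervention:
                g[base + 14 : base + 16] = rng.normal(0.0, pr.phi_scale, 2)
        z = {
            "z_pos": rng.standard_normal((self.n_subjects, 4)),
            "z_neg": rng.standard_normal((self.n_subjects, 4)),
        }
        return g, z

    def record(self, group, z, record_subjects: bool) -> dict[str, np.ndarray]:
        out = {}
        mus, sds, Rs, phis = [], [], [], []
        for vi in range(2):
            base = vi * _V_STRIDE
            mus.append(group[base : base + 4].copy())
            sds.append(np.exp(group[base + 4 : base + 8]))
            R = _mvn.unconstrained_to_corr(
                group[base + 8 : base + 14], 4
            )
            # report the cross-session same-dimension correlations and the
            # within-session cross-dimension correlation at baseline
            Rs.append(np.array([R[0, 2], R[1, 3], R[0, 1]]))
            if self.intervention:
                phis.append(group[base + 14 : base + 16].copy())
        out["mu"] = np.stack(mus)        # (valence, 4 cells)
        out["sigma"] = np.stack(sds)
        out["R"] = np.stack(Rs)          # (valence, 3)
        if self.intervention:
            out["phi_int"] = np.stack(phis)  # (valence, 2 dims)
        if record_subjects:
            out["theta"] = self.traits(group, z)
        return out

    labels = {
        "mu": [f"{v},{lab}" for v in VALENCES for lab in CELL_LABELS],
        "sigma": [f"{v},{lab}" for v in VALENCES for lab in CELL_LABELS],
        "R": [
            f"{v},{lab}"
            for v in VALENCES
            for lab in ("internal", "global", "internal-global,1")
        ],
        "phi_int": [f"{v},{d}" for v in VALENCES for d in DIMS],
    }


def fit_attribution(
    data: pd.DataFrame,
    mcmc: SamplerConfig | None = None,
    priors: AttributionPriorConfig | None = None,
    intervention: bool = True,
    check: bool = True,
) -> PosteriorFit:
    """Fit the hierarchical attribution model by MCMC.

    Draws include group means (``mu``, valence x cell), subject-SD scales
    (``sigma``), selected correlations (``R``: cross-session per dimension
    and baseline internal-global), intervention effects (``phi_int``,
    valence x dimension) and subject traits (``theta``, subjects x valence
    x cell).
    """
    mcmc = mcmc or SamplerConfig.test_profile()
    target = AttributionTarget(data, priors=priors, intervention=intervention)
    draws, info = run_mcmc(target, mcmc)
    fit = PosteriorFit(
        draws=draws,
        n_chains=mcmc.n_chains,
        n_warmup=mcmc.n_warmup,
        model="attribution",
        labels=target.labels,
        meta={
            "subject_ids": target.subject_ids,
            "active": target.active,
            "params": [f"{v},{d}" for v in VALENCES for d in DIMS],
            "subject_level": ("theta",),
            "target": target,
        },
        info=info,
    )
    if check:
        fit.check_convergence()
    return fit


def attribution_intervention_summary(
    fit: PosteriorFit, level: float = 0.90
) -> list[EffectSummary]:
    """Credible-interval summaries of the intervention effect on each
    dimension x valence trait, SMD-scaled by the posterior spread of
    session-2 subject traits."""
    if "phi_int" not in fit.draws:
        raise KeyError("fit contains no intervention-effect draws")
    phi = fit.pooled("phi_int")  # (draws, valence, dim)
    theta = fit.pooled("theta") if "theta" in fit.draws else None
    out = []
    for vi, v in enumerate(VALENCES):
        for di, d in enumerate(DIMS):
            smd = None
            if theta is not None:
                post_var = theta[:, :, vi, 2 + di].var(axis=1, ddof=1).mean()
                smd = float(phi[:, vi, di].mean() / np.sqrt(post_var))
            out.append(
                effect_from_draws(
                    f"phi_int[{d},{v}]", phi[:, vi, di], level, smd=smd
                )
            )
    return out


def endorsement_summary(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior mean and SD of each subject's endorsement probability per
    session, valence and dimension (the logistic transform of the trait)."""
    if "theta" not in fit.draws:
        raise KeyError("fit contains no subject trait draws")
    theta = fit.pooled("theta")  # (draws, n, valence, 4 cells)
    probs = expit(theta)
    rows = []
    sids = fit.meta["subject_ids"]
    for vi, v in enumerate(VALENCES):
        for ci, lab in enumerate(CELL_LABELS):
            dim, sess = lab.split(",")
            mean = probs[:, :, vi, ci].mean(axis=0)
            sd = probs[:, :, vi, ci].std(axis=0)
            for i, sid in enumerate(sids):
                rows.append(
                    {
                        "subject_id": sid,
                        "valence": v,
                        "dimension": dim,
                        "session": int(sess),
                        "p_mean": mean[i],
                        "p_sd": sd[i],
                    }
                )
    return pd.DataFrame(rows)
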