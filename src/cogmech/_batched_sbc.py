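"""Batched simulation-based-calibration runs.

SBC refits the same small model hundreds of times on independent
prior-predictive datasets. Fitting them one at a time is dominated by
Python/numpy call overhead at calibration sizes (tens of subjects), so this
module advances *all* replicate chains simultaneously: every state array
carries a leading dataset axis and each Metropolis update is accepted or
rejected per dataset (or per dataset x subject) in vectorized form. Each
replicate is still an independent, valid Markov chain targeting its own
posterior — the batching shares no information across datasets.

The moves mirror :mod:`cogmech.sampling`: vectorized subject random-walk and
preconditioned Crank-Nicolson updates, adaptive group-block random walks,
and likelihood-invariant recentering moves; adaptation freezes after warmup
and every chain starts at the prior draw that generated its dataset (a
stationary start).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from . import _mvn
from ._kernels import bernoulli_row_loglik

__all__ = ["batched_sbc_draws"]


# ---------------------------------------------------------------------------
# batched correlation utilities (fixed small dims, vectorized over datasets)
# ---------------------------------------------------------------------------


def _partials_to_corr_batch(p: np.ndarray, dim: int) -> np.ndarray:
    """Vine recursion vectorized over the leading axis; p is (K, n_pairs)."""
    K = p.shape[0]
    P = np.zeros((K, dim, dim))
    for idx, (i, j) in enumerate(_mvn.pair_indices(dim)):
        P[:, i, j] = p[:, idx]
    R = np.broadcast_to(np.eye(dim), (K, dim, dim)).copy()
    for i in range(dim - 1):
        for j in range(i + 1, dim):
            r = P[:, i, j].copy()
            for k in range(i - 1, -1, -1):
                r = r * np.sqrt(
                    (1.0 - P[:, k, j] ** 2) * (1.0 - P[:, k, i] ** 2)
                ) + P[:, k, i] * P[:, k, j]
            R[:, i, j] = R[:, j, i] = r
    return R


def _chol_batch(c: np.ndarray, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """(L, L^-1) of the correlation matrices implied by unconstrained c."""
    R = _partials_to_corr_batch(np.tanh(c), dim)
    R += 1e-10 * np.eye(dim)
    L = np.linalg.cholesky(R)
    return L, np.linalg.inv(L)


def _corr_log_prior_batch(c: np.ndarray, dim: int, eta: float) -> np.ndarray:
    b = _mvn.vine_beta_params(dim, eta)
    log1m = np.log(4.0) - 2.0 * np.logaddexp(c, -c)
    return log1m @ b


# ---------------------------------------------------------------------------
# model definitions
# ---------------------------------------------------------------------------


class _BatchRewardEffort:
    """K replicate two-session reward-effort hierarchies, 20-ish subjects.

    Group layout per dataset: mu(4), log sd(4), atanh r(2), phi(2).
    """

    group_dim = 12
    z_dims = {"subj": 4}

    def __init__(self, K, n_subjects, design, priors, rng):
        self.K = K
        self.n = n_subjects
        self.priors = priors
        noncatch = ~design.is_catch
        dr = (design.reward_hi - design.reward_lo)[noncatch].astype(float)
        de = (design.effort_hi - design.effort_lo)[noncatch]
        t = len(dr)
        # both sessions share the trial array
        self.dr = np.tile(dr, 2)[None, None, :]      # (1, 1, 2t)
        self.de = np.tile(de, 2)[None, None, :]
        self.s2 = np.repeat([False, True], t)[None, None, :]
        self.active = np.arange(self.n) < self.n // 2
        self.T = 2 * t

        self.truth_group = self._sample_prior_group(rng)
        self.truth_z = {"subj": rng.standard_normal((K, self.n, 4))}
        params = self.subject_params(self.truth_group, self.truth_z)
        logit = self._logit(params)
        self.sign = np.where(
            rng.random(logit.shape) < expit(logit), 1.0, -1.0
        )

        self.group_blocks = [
            ("loc", np.array([0, 1, 2, 3, 10, 11])),
            ("scale", np.arange(4, 10)),
        ]
        self.recenter_blocks = [("r_loc", self.group_blocks[0][1], "loc"),
                                ("r_scale", self.group_blocks[1][1], "scale")]
        self.z_block_names = ["subj"]

    # -- priors ------------------------------------------------------------
    def _sample_prior_group(self, rng):
        pr = self.priors
        g = np.empty((self.K, 12))
        g[:, 0:4] = rng.normal(pr.mu_loc, pr.mu_scale, (self.K, 4))
        g[:, 4:8] = np.log(
            np.abs(rng.normal(0.0, pr.sd_scale, (self.K, 4))) + 1e-8
        )
        for j in (8, 9):
            p = 2.0 * rng.beta(1.0, 1.0, self.K) - 1.0
            g[:, j] = np.arctanh(np.clip(p, -0.999999, 0.999999))
        g[:, 10:12] = rng.normal(0.0, pr.phi_scale, (self.K, 2))
        return g

    def group_log_prior(self, g):
        pr = self.priors
        mu = (g[:, 0:4] - pr.mu_loc) / pr.mu_scale
        lp = -0.5 * np.einsum("ki,ki->k", mu, mu)
        sd = np.exp(g[:, 4:8])
        lp += g[:, 4:8].sum(1) - 0.5 * np.einsum(
            "ki,ki->k", sd / pr.sd_scale, sd / pr.sd_scale
        )
        # two independent 2x2 correlations, one per parameter
        lp += _corr_log_prior_batch(g[:, 8:9], 2, pr.lkj_eta)
        lp += _corr_log_prior_batch(g[:, 9:10], 2, pr.lkj_eta)
        phi = g[:, 10:12] / np.asarray(pr.phi_scale)
        lp += -0.5 * np.einsum("ki,ki->k", phi, phi)
        return lp

    # -- parameters and likelihood ------------------------------------------
    def subject_params(self, g, z):
        """(K, n, 2 params, 2 sessions)."""
        mu = g[:, 0:4].reshape(self.K, 2, 2)
        sd = np.exp(g[:, 4:8]).reshape(self.K, 2, 2)
        rho = np.tanh(g[:, 8:10])
        zs = z["subj"]
        out = np.empty((self.K, self.n, 2, 2))
        for k in range(2):
            z1 = zs[:, :, 2 * k]
            z2 = zs[:, :, 2 * k + 1]
            off2 = rho[:, k, None] * z1 + np.sqrt(
                np.maximum(1.0 - rho[:, k, None] ** 2, 1e-12)
            ) * z2
            out[:, :, k, 0] = mu[:, None, k, 0] + sd[:, None, k, 0] * z1
            out[:, :, k, 1] = mu[:, None, k, 1] + sd[:, None, k, 1] * off2
            out[:, self.active, k, 1] += g[:, 10 + k, None]
        return out

    def _logit(self, params):
        rew = np.where(self.s2, params[:, :, 0, 1:2], params[:, :, 0, 0:1])
        eff = np.where(self.s2, params[:, :, 1, 1:2], params[:, :, 1, 0:1])
        return rew * self.dr - eff * self.de

    def loglik(self, g, z):
        logit = self._logit(self.subject_params(g, z))
        flat = bernoulli_row_loglik(
            logit.reshape(-1, self.T), self.sign.reshape(-1, self.T)
        )
        return flat.reshape(self.K, self.n)

    # -- recentering ---------------------------------------------------------
    def _offsets(self, g, z):
        sd = np.exp(g[:, 4:8]).reshape(self.K, 2, 2)
        rho = np.tanh(g[:, 8:10])
        zs = z["subj"]
        o = np.empty_like(zs)
        for k in range(2):
            z1 = zs[:, :, 2 * k]
            z2 = zs[:, :, 2 * k + 1]
            o[:, :, 2 * k] = sd[:, None, k, 0] * z1
            o[:, :, 2 * k + 1] = sd[:, None, k, 1] * (
                rho[:, k, None] * z1
                + np.sqrt(np.maximum(1 - rho[:, k, None] ** 2, 1e-12)) * z2
            )
        return o

    def _z_from_offsets(self, g, o):
        sd = np.exp(g[:, 4:8]).reshape(self.K, 2, 2)
        rho = np.tanh(g[:, 8:10])
        zs = np.empty_like(o)
        for k in range(2):
            z1 = o[:, :, 2 * k] / sd[:, None, k, 0]
            zs[:, :, 2 * k] = z1
            zs[:, :, 2 * k + 1] = (
                o[:, :, 2 * k + 1] / sd[:, None, k, 1] - rho[:, k, None] * z1
            ) / np.sqrt(np.maximum(1 - rho[:, k, None] ** 2, 1e-12))
        return zs

    def _shift(self, g):
        shift = np.repeat(g[:, None, 0:4], self.n, axis=1)
        shift[:, self.active, 1] += g[:, 10, None]
        shift[:, self.active, 3] += g[:, 11, None]
        return shift

    def _logdet_scale(self, g):
        rho = np.tanh(g[:, 8:10])
        return g[:, 4:8].sum(1) + 0.5 * np.log(
            np.maximum(1 - rho**2, 1e-12)
        ).sum(1)

    def recenter(self, kind, g_old, g_new, z):
        o = self._offsets(g_old, z)
        if kind == "loc":
            o = o + self._shift(g_old) - self._shift(g_new)
            jac = np.zeros(self.K)
        else:
            jac = self.n * (
                self._logdet_scale(g_old) - self._logdet_scale(g_new)
            )
        return {"subj": self._z_from_offsets(g_new, o)}, jac

    # -- recording -----------------------------------------------------------
    def monitored_names(self, n_subj_monitored):
        names = (
            [f"mu[{i},{j}]" for i in range(2) for j in range(2)]
            + [f"sigma[{i},{j}]" for i in range(2) for j in range(2)]
            + ["R[0]", "R[1]", "phi_int[0]", "phi_int[1]"]
            + [f"subj[{p},1,0]" for p in range(n_subj_monitored)]
        )
        return names

    def monitored_values(self, g, z, n_subj_monitored):
        """(K, P) natural-scale monitored quantities."""
        cols = [
            g[:, 0], g[:, 1], g[:, 2], g[:, 3],
            np.exp(g[:, 4]), np.exp(g[:, 5]), np.exp(g[:, 6]),
            np.exp(g[:, 7]),
            np.tanh(g[:, 8]), np.tanh(g[:, 9]), g[:, 10], g[:, 11],
        ]
        params = self.subject_params(g, z)
        for p in range(n_subj_monitored):
            cols.append(params[:, p, 1, 0])
        return np.stack(cols, axis=1)


class _BatchAttribution:
    """K replicate attribution hierarchies.

    Group layout per dataset and valence v (stride 16): mu(4), log sd(4),
    atanh partials(6), phi(2).
    """

    group_dim = 32
    z_dims = {"z_pos": 4, "z_neg": 4}

    def __init__(self, K, n_subjects, design, priors, rng):
        self.K = K
        self.n = n_subjects
        self.priors = priors
        self.active = np.arange(self.n) < self.n // 2
        n_per = {"pos": design.n_positive, "neg": design.n_negative}
        # shared template: per valence, (session, scenario) x two codes;
        # cell index within a valence is s*2 + dim
        self.cells = {}
        for val in ("pos", "neg"):
            cells = []
            for s in (0, 1):
                cells.extend([s * 2] * n_per[val])
                cells.extend([s * 2 + 1] * n_per[val])
            self.cells[val] = np.asarray(cells)
        self.T = {v: len(self.cells[v]) for v in ("pos", "neg")}

        self.truth_group = self._sample_prior_group(rng)
        self.truth_z = {
            "z_pos": rng.standard_normal((K, self.n, 4)),
            "z_neg": rng.standard_normal((K, self.n, 4)),
        }
        self.sign = {}
        for vi, val in enumerate(("pos", "neg")):
            th = self.traits_valence(self.truth_group, self.truth_z, vi)
            logit = th[:, :, self.cells[val]]
            self.sign[val] = np.where(
                rng.random(logit.shape) < expit(logit), 1.0, -1.0
            )

        self.group_blocks = []
        self.recenter_blocks = []
        for vi, v in enumerate(("pos", "neg")):
            base = vi * 16
            loc = np.array([base + i for i in (0, 1, 2, 3, 14, 15)])
            scale = np.arange(base + 4, base + 14)
            self.group_blocks.append((f"loc_{v}", loc))
            self.group_blocks.append((f"scale_{v}", scale))
            self.recenter_blocks.append((f"rloc_{v}", loc, ("loc", vi)))
            self.recenter_blocks.append((f"rscale_{v}", scale,
                                         ("scale", vi)))
        self.z_block_names = ["z_pos", "z_neg"]
        self.block_valence = {
            "loc_pos": 0, "scale_pos": 0, "loc_neg": 1, "scale_neg": 1,
            "z_pos": 0, "z_neg": 1,
        }

    def _sample_prior_group(self, rng):
        pr = self.priors
        mu_loc = np.asarray(pr.mu_loc).reshape(2, 4)
        g = np.empty((self.K, 32))
        b = _mvn.vine_beta_params(4, pr.lkj_eta)
        for vi in range(2):
            base = vi * 16
            g[:, base : base + 4] = rng.normal(
                mu_loc[vi], pr.mu_scale, (self.K, 4)
            )
            g[:, base + 4 : base + 8] = np.log(
                np.abs(rng.normal(0.0, pr.sd_scale, (self.K, 4))) + 1e-8
            )
            p = 2.0 * rng.beta(b, b, (self.K, 6)) - 1.0
            g[:, base + 8 : base + 14] = np.arctanh(
                np.clip(p, -0.999999, 0.999999)
            )
            g[:, base + 14 : base + 16] = rng.normal(
                0.0, pr.phi_scale, (self.K, 2)
            )
        return g

    def group_log_prior_valence(self, g, vi):
        pr = self.priors
        mu_loc = np.asarray(pr.mu_loc).reshape(2, 4)
        base = vi * 16
        mu = (g[:, base : base + 4] - mu_loc[vi]) / pr.mu_scale
        lp = -0.5 * np.einsum("ki,ki->k", mu, mu)
        u = g[:, base + 4 : base + 8]
        sd = np.exp(u)
        lp += u.sum(1) - 0.5 * np.einsum("ki,ki->k", sd, sd) / pr.sd_scale**2
        lp += _corr_log_prior_batch(
            g[:, base + 8 : base + 14], 4, pr.lkj_eta
        )
        phi = g[:, base + 14 : base + 16]
        lp += -0.5 * np.einsum("ki,ki->k", phi, phi) / pr.phi_scale**2
        return lp

    def group_log_prior(self, g):
        return self.group_log_prior_valence(g, 0) + \
            self.group_log_prior_valence(g, 1)

    def _chol(self, g, vi):
        base = vi * 16
        return _chol_batch(g[:, base + 8 : base + 14], 4)

    def traits_valence(self, g, z, vi):
        base = vi * 16
        mu = g[:, base : base + 4]
        sd = np.exp(g[:, base + 4 : base + 8])
        L, _ = self._chol(g, vi)
        zv = z["z_pos" if vi == 0 else "z_neg"]
        out = mu[:, None, :] + np.einsum("knj,kij->kni", zv, L) * sd[:, None, :]
        out[:, self.active, 2] += g[:, base + 14, None]
        out[:, self.active, 3] += g[:, base + 15, None]
        return out

    def loglik_valence(self, g, z, vi):
        val = ("pos", "neg")[vi]
        th = self.traits_valence(g, z, vi)
        logit = th[:, :, self.cells[val]]
        t = self.T[val]
        flat = bernoulli_row_loglik(
            logit.reshape(-1, t), self.sign[val].reshape(-1, t)
        )
        return flat.reshape(self.K, self.n)

    # -- recentering ---------------------------------------------------------
    def _offsets(self, g, z, vi):
        base = vi * 16
        sd = np.exp(g[:, base + 4 : base + 8])
        L, _ = self._chol(g, vi)
        zv = z["z_pos" if vi == 0 else "z_neg"]
        return np.einsum("knj,kij->kni", zv, L) * sd[:, None, :]

    def _z_from_offsets(self, g, o, vi):
        base = vi * 16
        sd = np.exp(g[:, base + 4 : base + 8])
        _, Linv = self._chol(g, vi)
        return np.einsum("knj,kij->kni", o / sd[:, None, :], Linv)

    def _shift(self, g, vi):
        base = vi * 16
        shift = np.repeat(g[:, None, base : base + 4], self.n, axis=1)
        shift[:, self.active, 2] += g[:, base + 14, None]
        shift[:, self.active, 3] += g[:, base + 15, None]
        return shift

    def _logdet_scale(self, g, vi):
        base = vi * 16
        L, _ = self._chol(g, vi)
        diag = np.diagonal(L, axis1=1, axis2=2)
        return g[:, base + 4 : base + 8].sum(1) + np.log(
            np.maximum(diag, 1e-150)
        ).sum(1)

    def recenter(self, kind, g_old, g_new, z):
        what, vi = kind
        key = "z_pos" if vi == 0 else "z_neg"
        o = self._offsets(g_old, z, vi)
        if what == "loc":
            o = o + self._shift(g_old, vi) - self._shift(g_new, vi)
            jac = np.zeros(self.K)
        else:
            jac = self.n * (
                self._logdet_scale(g_old, vi) - self._logdet_scale(g_new, vi)
            )
        return {key: self._z_from_offsets(g_new, o, vi)}, jac

    # -- recording -----------------------------------------------------------
    def monitored_names(self, n_subj_monitored):
        names = []
        for vi in range(2):
            names += [f"mu[{vi},{j}]" for j in range(4)]
            names += [f"sigma[{vi},{j}]" for j in range(4)]
            names += [f"R[{vi},0]", f"R[{vi},1]", f"R[{vi},2]"]
            names += [f"phi_int[{vi},0]", f"phi_int[{vi},1]"]
        names += [f"theta[{p},0,0]" for p in range(n_subj_monitored)]
        return names

    def monitored_values(self, g, z, n_subj_monitored):
        cols = []
        for vi in range(2):
            base = vi * 16
            for j in range(4):
                cols.append(g[:, base + j])
            for j in range(4):
                cols.append(np.exp(g[:, base + 4 + j]))
            R = _partials_to_corr_batch(
                np.tanh(g[:, base + 8 : base + 14]), 4
            )
            cols += [R[:, 0, 2], R[:, 1, 3], R[:, 0, 1]]
            cols += [g[:, base + 14], g[:, base + 15]]
        th = self.traits_valence(g, z, 0)
        for p in range(n_subj_monitored):
            cols.append(th[:, p, 0])
        return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# batched driver
# ---------------------------------------------------------------------------

_TARGET_SCALAR = 0.44
_TARGET_MULTI = 0.27


class _BatchBlockState:
    """Adaptive multivariate proposal state, one instance per block,
    vectorized over datasets."""

    def __init__(self, K, idx):
        self.idx = idx
        d = len(idx)
        self.log_scale = np.full(K, np.log(2.38 / np.sqrt(d)) - 1.0)
        self.chol = np.broadcast_to(np.eye(d), (K, d, d)).copy()
        self._n = 0
        self._mean = np.zeros((K, d))
        self._m2 = np.zeros((K, d, d))

    def propose(self, rng, K):
        eps = rng.standard_normal((K, len(self.idx)))
        step = np.einsum("kij,kj->ki", self.chol, eps)
        return np.exp(self.log_scale)[:, None] * step

    def update_history(self, value):
        self._n += 1
        delta = value - self._mean
        self._mean += delta / self._n
        self._m2 += np.einsum("ki,kj->kij", delta, value - self._mean)

    def refresh_chol(self):
        if self._n < 2 * len(self.idx) + 10:
            return
        cov = self._m2 / (self._n - 1)
        cov = cov + 1e-8 * np.eye(len(self.idx))
        try:
            self.chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            pass

    def adapt(self, aprob, sweep):
        rate = (sweep + 20.0) ** -0.6
        self.log_scale += rate * (aprob - _TARGET_MULTI)


def batched_sbc_draws(
    model_kind: str,
    n_datasets: int,
    n_subjects: int,
    n_draws: int,
    warmup: int,
    steps_per_draw: int,
    seed: int,
    n_subj_monitored: int = 5,
    priors=None,
    design=None,
):
    """Run K replicate chains in lockstep; returns (names, truths, draws).

    ``truths`` is (K, P); ``draws`` is (K, D, P) with D = ``n_draws``
    retained states separated by ``steps_per_draw`` sweeps after ``warmup``
    sweeps. Chains start at the prior draws that generated their data.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if model_kind == "reward-effort":
        from .reward_effort import PriorConfig
        from .synthetic import generate_task_design

        model = _BatchRewardEffort(
            n_datasets, n_subjects,
            design or generate_task_design(seed=0),
            priors or PriorConfig.pilot_informed(), rng,
        )
        valence_of = {}
        loglik_parts = [lambda g, z: model.loglik(g, z)]
        part_of_block = {name: (0,) for name in
                         ("loc", "scale", "subj")}
    elif model_kind == "attribution":
        from .attribution import AttributionPriorConfig
        from .synthetic import AttributionDesign

        model = _BatchAttribution(
            n_datasets, n_subjects, design or AttributionDesign(),
            priors or AttributionPriorConfig.pilot_informed(), rng,
        )
        loglik_parts = [
            lambda g, z: model.loglik_valence(g, z, 0),
            lambda g, z: model.loglik_valence(g, z, 1),
        ]
        part_of_block = {
            "loc_pos": (0,), "scale_pos": (0,), "z_pos": (0,),
            "loc_neg": (1,), "scale_neg": (1,), "z_neg": (1,),
        }
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")

    K, n = model.K, model.n
    g = model.truth_group.copy()
    z = {k: v.copy() for k, v in model.truth_z.items()}
    ll = [part(g, z) for part in loglik_parts]
    glp = model.group_log_prior(g)

    z_scales = {name: np.full((K, n), 0.3) for name in model.z_block_names}
    z_dim = {name: np.ones((K, model.z_dims[name]))
             for name in model.z_block_names}
    z_dim_var = {name: np.ones((K, model.z_dims[name]))
                 for name in model.z_block_names}
    pcn_beta = {name: np.full(K, 0.3) for name in model.z_block_names}
    g_states = {name: _BatchBlockState(K, idx)
                for name, idx in model.group_blocks}
    r_states = {name: _BatchBlockState(K, idx)
                for name, idx, _ in model.recenter_blocks}

    truths = model.monitored_values(model.truth_group, model.truth_z,
                                    n_subj_monitored)
    names = model.monitored_names(n_subj_monitored)
    draws = np.empty((K, n_draws, len(names)))
    d_idx = 0

    total = warmup + n_draws * steps_per_draw
    for sweep in range(total):
        warm = sweep < warmup
        rate = (sweep + 20.0) ** -0.6

        # --- subject blocks: random walk then pCN ---
        for name in model.z_block_names:
            parts = part_of_block[name]
            dim = model.z_dims[name]
            cur = z[name]

            step = z_scales[name][:, :, None] * z_dim[name][:, None, :]
            prop = cur + step * rng.standard_normal((K, n, dim))
            z_prop = dict(z)
            z_prop[name] = prop
            ll_prop = {i: loglik_parts[i](g, z_prop) for i in parts}
            dlp = sum(ll_prop[i] - ll[i] for i in parts)
            dlp += 0.5 * (
                np.einsum("knj,knj->kn", cur, cur)
                - np.einsum("knj,knj->kn", prop, prop)
            )
            acc = np.log(rng.random((K, n))) < dlp
            cur[acc] = prop[acc]
            for i in parts:
                ll[i] = np.where(acc, ll_prop[i], ll[i])
            if warm:
                aprob = np.exp(np.minimum(dlp, 0.0))
                z_scales[name] *= np.exp(rate * (aprob - _TARGET_SCALAR))
                zv = z_dim_var[name]
                zv += 0.02 * ((cur**2).mean(axis=1) - zv)
                if sweep % 50 == 49:
                    s = np.sqrt(np.maximum(zv, 1e-4))
                    z_dim[name] = s / np.exp(
                        np.log(s).mean(axis=1, keepdims=True)
                    )

            beta = pcn_beta[name][:, None, None]
            prop = np.sqrt(1.0 - beta**2) * cur + beta * rng.standard_normal(
                (K, n, dim)
            )
            z_prop[name] = prop
            ll_prop = {i: loglik_parts[i](g, z_prop) for i in parts}
            dlp = sum(ll_prop[i] - ll[i] for i in parts)
            acc = np.log(rng.random((K, n))) < dlp
            cur[acc] = prop[acc]
            for i in parts:
                ll[i] = np.where(acc, ll_prop[i], ll[i])
            if warm:
                aprob = np.exp(np.minimum(dlp, 0.0)).mean(axis=1)
                pcn_beta[name] = np.clip(
                    pcn_beta[name] * np.exp(rate * (aprob - 0.3)),
                    0.01, 0.99,
                )

        # --- group blocks ---
        for name, idx in model.group_blocks:
            st = g_states[name]
            parts = part_of_block[name]
            g_prop = g.copy()
            g_prop[:, idx] += st.propose(rng, K)
            glp_prop = model.group_log_prior(g_prop)
            ll_prop = {i: loglik_parts[i](g_prop, z) for i in parts}
            dlp = (glp_prop - glp) + sum(
                (ll_prop[i] - ll[i]).sum(axis=1) for i in parts
            )
            acc = np.log(rng.random(K)) < dlp
            g[acc] = g_prop[acc]
            glp = np.where(acc, glp_prop, glp)
            for i in parts:
                ll[i] = np.where(acc[:, None], ll_prop[i], ll[i])
            if warm:
                st.adapt(np.exp(np.minimum(dlp, 0.0)), sweep)
                st.update_history(g[:, idx])
                if sweep % 100 == 99:
                    st.refresh_chol()

        # --- recentering moves (likelihood-invariant) ---
        for name, idx, kind in model.recenter_blocks:
            st = r_states[name]
            g_prop = g.copy()
            g_prop[:, idx] += st.propose(rng, K)
            glp_prop = model.group_log_prior(g_prop)
            z_new, jac = model.recenter(kind, g, g_prop, z)
            dz = sum(
                0.5 * (
                    np.einsum("knj,knj->k", z[k], z[k])
                    - np.einsum("knj,knj->k", z_new[k], z_new[k])
                )
                for k in z_new
            )
            dlp = (glp_prop - glp) + dz + jac
            acc = np.log(rng.random(K)) < dlp
            g[acc] = g_prop[acc]
            glp = np.where(acc, glp_prop, glp)
            for k, v in z_new.items():
                z[k][acc] = v[acc]
            if warm:
                st.adapt(np.exp(np.minimum(dlp, 0.0)), sweep)
                st.update_history(g[:, idx])
                if sweep % 100 == 99:
                    st.refresh_chol()

        # periodic refresh against floating-point drift (recentering keeps
        # the likelihood fixed only up to rounding)
        if sweep % 200 == 199:
            ll = [part(g, z) for part in loglik_parts]

        if not warm and (sweep - warmup + 1) % steps_per_draw == 0:
            draws[:, d_idx, :] = model.monitored_values(
                g, z, n_subj_monitored
            )
            d_idx += 1

    return names, truths, draws[:, :d_idx, :]
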