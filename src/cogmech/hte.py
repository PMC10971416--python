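"""Heterogeneity of treatment effects and repeated-measures power analysis.

The HTE decomposition compares the standardized SDs of pre-to-post change
scores in the active and control arms: assuming the control arm's change
variance reflects occasion-to-occasion variability plus measurement error,
the SD of individual responses to active treatment is ``SD_IR =
sqrt(SD_Act^2 - SD_Con^2)``, with an approximately normal sampling
distribution used for its confidence interval. Standardized SD_IR values of
0.1, 0.3 and 0.6 mark small, moderate and large individual-response effects.

Power for the group x time interaction of a two-group, two-occasion
repeated-measures ANOVA uses the noncentral-F formulation with Cohen's
``f = d / 2`` and noncentrality ``lambda = f^2 * N * m / (1 - rho)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .results import PosteriorFit

__all__ = [
    "HTEResult",
    "PowerSpec",
    "change_scores",
    "sd_individual_response",
    "hte_from_fit",
    "rm_interaction_power",
    "required_sample_size",
]

EFFECT_THRESHOLDS = (0.1, 0.3, 0.6)  # small / moderate / large


@dataclass(frozen=True)
class HTEResult:
    SD_Act: float
    SD_Con: float
    DF_Act: int
    DF_Con: int
    SD_IR: float
    SD_IRse: float
    CI95: tuple[float, float]
    effect_class: str
    no_heterogeneity: bool = False

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["CI95"] = list(self.CI95)
        return d


def _classify(sd_ir: float) -> str:
    small, moderate, large = EFFECT_THRESHOLDS
    if sd_ir < small:
        return "none"
    if sd_ir < moderate:
        return "small"
    if sd_ir < large:
        return "moderate"
    return "large"


def change_scores(
    fit: PosteriorFit,
    parameter: str = "effSens",
    baseline_sd: str = "pooled",
) -> pd.DataFrame:
    """Standardized per-subject change scores by arm.

    Change is the difference in posterior-mean subject parameter between
    sessions, standardized by the SD across subjects of the session-1
    (baseline) posterior means — pooled across arms by default, per-arm with
    ``baseline_sd='per-arm'``.
    """
    if "subj" in fit.draws:
        mean_params = fit.pooled("subj").mean(axis=0)  # (n, param, session)
        params = list(fit.meta["params"])
        k = params.index(parameter)
        s1 = mean_params[:, k, 0]
        s2 = mean_params[:, k, 1]
    elif "theta" in fit.draws:
        mean_theta = fit.pooled("theta").mean(axis=0)  # (n, val, 4)
        labels = fit.meta["params"]  # e.g. 'pos,internal'
        v, d = parameter.split(",")
        vi = ("pos", "neg").index(v)
        di = ("internal", "global").index(d)
        s1 = mean_theta[:, vi, 0 + di]
        s2 = mean_theta[:, vi, 2 + di]
    else:
        raise KeyError("fit carries no subject-level draws")
    active = fit.meta["active"]
    if active.sum() == 0 or active.sum() == len(active):
        raise ValueError("change-score decomposition needs two arms")

    change = s2 - s1
    if baseline_sd == "pooled":
        denom = np.std(s1, ddof=1)
        z = change / denom
    elif baseline_sd == "per-arm":
        z = np.empty_like(change)
        for mask in (active, ~active):
            z[mask] = change[mask] / np.std(s1[mask], ddof=1)
    else:
        raise ValueError("baseline_sd must be 'pooled' or 'per-arm'")
    return pd.DataFrame(
        {
            "subject_id": fit.meta["subject_ids"],
            "arm": np.where(active, "active", "control"),
            "change": z,
        }
    )


def sd_individual_response(
    sd_act: float,
    sd_con: float,
    df_act: int,
    df_con: int,
    allow_negative: bool = False,
) -> HTEResult:
    """Individual-response SD with its normal-approximation 95% CI.

    ``SD_IRse = sqrt(2*(SD_Act^4/DF_Act + SD_Con^4/DF_Con))`` and the CI is
    ``SD_IR +/- 1.96*SD_IRse``. When the active-arm variance is smaller
    than the control-arm variance the point estimate is clamped at 0 and
    flagged (``allow_negative=True`` instead reports the signed square root
    of the variance difference).
    """
    if sd_act < 0 or sd_con < 0:
        raise ValueError("SDs must be non-negative")
    if df_act < 1 or df_con < 1:
        raise ValueError("degrees of freedom must be >= 1")
    var_diff = sd_act**2 - sd_con**2
    no_het = var_diff < 0
    if no_het and not allow_negative:
        sd_ir = 0.0
    else:
        sd_ir = float(np.sign(var_diff) * np.sqrt(abs(var_diff)))
    se = float(np.sqrt(2.0 * (sd_act**4 / df_act + sd_con**4 / df_con)))
    ci = (sd_ir - 1.96 * se, sd_ir + 1.96 * se)
    return HTEResult(
        SD_Act=float(sd_act),
        SD_Con=float(sd_con),
        DF_Act=int(df_act),
        DF_Con=int(df_con),
        SD_IR=sd_ir,
        SD_IRse=se,
        CI95=ci,
        effect_class=_classify(max(sd_ir, 0.0)),
        no_heterogeneity=bool(no_het),
    )


def hte_from_fit(
    fit: PosteriorFit, parameter: str = "effSens", baseline_sd: str = "pooled"
) -> HTEResult:
    """Change-score decomposition of a two-arm fit for one parameter."""
    cs = change_scores(fit, parameter, baseline_sd)
    act = cs.loc[cs["arm"] == "active", "change"]
    con = cs.loc[cs["arm"] == "control", "change"]
    return sd_individual_response(
        act.std(ddof=1), con.std(ddof=1), len(act) - 1, len(con) - 1
    )


@dataclass(frozen=True)
class PowerSpec:
    """Between-within interaction power specification.

    ``d`` is the standardized effect size of the group difference in
    change; the power convention converts it as ``f = d/2``. ``rho`` is the
    correlation across repeated measures, ``m`` the measures per subject,
    ``N`` the total sample size across both groups.
    """

    d: float
    N: int
    m: int = 2
    rho: float = 0.5
    alpha: float = 0.05
    groups: int = 2

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not -1 < self.rho < 1:
            raise ValueError("rho must be in (-1, 1)")
        if self.m < 2:
            raise ValueError("repeated-measures design needs m >= 2")
        if self.N <= self.groups:
            raise ValueError("N must exceed the number of groups")

    @property
    def f(self) -> float:
        return self.d / 2.0

    @property
    def noncentrality(self) -> float:
        return self.f**2 * self.N * self.m / (1.0 - self.rho)


def rm_interaction_power(spec: PowerSpec) -> float:
    """Power of the group x time interaction F test.

    Noncentral F with ``df1 = (groups-1)(m-1)``, ``df2 = N - groups`` and
    noncentrality ``f^2 * N * m / (1 - rho)``; with d = 0 the rejection
    rate equals alpha.
    """
    df1 = (spec.groups - 1) * (spec.m - 1)
    df2 = spec.N - spec.groups
    crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    lam = spec.noncentrality
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def required_sample_size(
    d: float,
    target_power: float = 0.95,
    m: int = 2,
    rho: float = 0.5,
    alpha: float = 0.05,
    groups: int = 2,
    n_max: int = 100_000,
) -> int:
    """Smallest total N (a multiple of the group count) reaching the target
    interaction power."""
    if not 0 < target_power < 1:
        raise ValueError("target power must be in (0, 1)")
    if d == 0:
        raise ValueError("power above alpha is unreachable with d = 0")
    n = 2 * groups
    while n <= n_max:
        p = rm_interaction_power(
            PowerSpec(d=d, N=n, m=m, rho=rho, alpha=alpha, groups=groups)
        )
        if p >= target_power:
            return n
        n += groups
    raise ValueError("target power not reached below n_max")
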