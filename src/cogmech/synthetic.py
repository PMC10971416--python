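"""Synthetic cohorts for the reward-effort and causal-attribution tasks.

Generates task designs, two-session randomized cohorts, trial-level choices,
attribution responses, ordinal symptom-item responses and the covariates the
exclusion rules operate on (catch-trial performance, response times, option
positions), all fully seeded.

The default design constants reproduce the published tasks: 44 reward-effort
choice trials in four blocks including two catch trials, rewards of three to
seven coins and efforts of 0.25-0.95 of each participant's calibrated
maximum; 32 attribution scenarios (16 positive, 16 negative) in two blocks,
each offering the four internal/external x global/specific explanations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from ._mvn import corr_cholesky

__all__ = [
    "DesignError",
    "TrialArray",
    "AttributionDesign",
    "CohortConfig",
    "Item",
    "ItemBank",
    "generate_task_design",
    "default_reward_effort_cohort",
    "default_attribution_cohort",
    "simulate_reward_effort_cohort",
    "simulate_attribution_cohort",
    "default_item_banks",
    "simulate_item_responses",
    "simulate_joint_cohort",
    "apply_exclusion_rules",
    "ExclusionReport",
]

REWARD_RANGE = (3, 7)
EFFORT_RANGE = (0.25, 0.95)
N_EFFORT_LEVELS = 8


class DesignError(ValueError):
    pass


class SchemaError(KeyError):
    pass


# ---------------------------------------------------------------------------
# Task designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialArray:
    """Offer structure of one reward-effort session.

    The higher-reward option's effort is stored in ``effort_hi``. Non-catch
    trials are nondominated (more reward costs strictly more effort); catch
    trials offer the highest reward at the lowest effort, so the
    higher-reward option dominates.
    """

    block: np.ndarray
    trial: np.ndarray
    reward_hi: np.ndarray
    reward_lo: np.ndarray
    effort_hi: np.ndarray
    effort_lo: np.ndarray
    is_catch: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.block)

    @property
    def n_catch(self) -> int:
        return int(self.is_catch.sum())

    def validate(self) -> None:
        reg = ~self.is_catch
        if not np.all(self.reward_hi > self.reward_lo):
            raise DesignError("higher-reward option must offer more reward")
        if not np.all(self.effort_hi[reg] > self.effort_lo[reg]):
            raise DesignError("non-catch trials must be nondominated")
        if not np.all(self.effort_hi[self.is_catch] < self.effort_lo[self.is_catch]):
            raise DesignError("catch trials must be dominated")
        lo, hi = REWARD_RANGE
        if self.reward_lo.min() < lo or self.reward_hi.max() > hi:
            raise DesignError(f"rewards must lie in {REWARD_RANGE}")
        e0, e1 = EFFORT_RANGE
        efforts = np.concatenate([self.effort_hi, self.effort_lo])
        if efforts.min() < e0 - 1e-12 or efforts.max() > e1 + 1e-12:
            raise DesignError(f"efforts must lie in {EFFORT_RANGE}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": self.block,
                "trial": self.trial,
                "reward_hi": self.reward_hi,
                "reward_lo": self.reward_lo,
                "effort_hi": self.effort_hi,
                "effort_lo": self.effort_lo,
                "is_catch": self.is_catch.astype(int),
            }
        )


def generate_task_design(
    n_blocks: int = 4,
    trials_per_block: int = 11,
    n_catch: int = 2,
    reward_levels: tuple[int, int] = REWARD_RANGE,
    n_effort_levels: int = N_EFFORT_LEVELS,
    effort_range: tuple[float, float] = EFFORT_RANGE,
    seed: int = 0,
) -> TrialArray:
    """Seeded random offer array for one reward-effort session.

    Non-catch offers pair a lower-reward/lower-effort option with a
    higher-reward/higher-effort one; catch trials place the maximal reward
    at the minimal effort and are positioned in distinct blocks.

    Offer sampling emulates a design optimized for parameter recovery.
    Offers mix two trial types: effort-decisive trials (about two thirds)
    pair a one-coin reward difference with a large effort separation, so
    choices sit near indifference where they carry maximal information
    about effort sensitivity; reward-decisive trials pair a several-coin
    difference with a small effort separation, anchoring reward
    sensitivity. Mixing the types anti-correlates the reward and effort
    differences across trials, which decorrelates the two sensitivities in
    the likelihood (a single offer distribution leaves them nearly
    collinear, inflating effort-sensitivity uncertainty several-fold).
    """
    rng = np.random.default_rng(seed)
    r_lo, r_hi = reward_levels
    rewards = np.arange(r_lo, r_hi + 1)
    efforts = np.linspace(*effort_range, n_effort_levels)
    if len(rewards) < 2 or n_effort_levels < 2:
        raise DesignError(
            "need at least two reward and two effort levels for "
            "nondominated offers"
        )
    total = n_blocks * trials_per_block
    if n_catch > total:
        raise DesignError("more catch trials than trials")
    if n_catch > n_blocks:
        raise DesignError("catch trials must sit in distinct blocks")

    catch_blocks = rng.choice(n_blocks, size=n_catch, replace=False)
    catch_pos = {
        (int(b), int(rng.integers(trials_per_block))) for b in catch_blocks
    }
    n_lv = n_effort_levels
    rows = []
    for b in range(n_blocks):
        for t in range(trials_per_block):
            if (b, t) in catch_pos:
                # dominant option: highest reward for lowest effort
                other_r = rng.choice(rewards[:-1])
                other_e = rng.choice(efforts[1:])
                rows.append((b, t, rewards[-1], other_r, efforts[0],
                             other_e, True))
            elif rng.random() < 0.70:
                # effort-decisive: one extra coin, large effort split
                ra = int(rng.choice(rewards[:-1]))
                d_e = int(rng.choice([n_lv - 2, n_lv - 1], p=[0.15, 0.85]))
                ei = int(rng.integers(n_lv - d_e))
                rows.append((b, t, ra + 1, ra, efforts[ei + d_e],
                             efforts[ei], False))
            else:
                # reward-decisive: several coins, small effort split
                d_r = int(rng.choice(np.arange(2, len(rewards))))
                ra = int(rng.choice(rewards[: len(rewards) - d_r]))
                d_e = int(rng.choice([1, 2]))
                ei = int(rng.integers(n_lv - d_e))
                rows.append((b, t, ra + d_r, ra, efforts[ei + d_e],
                             efforts[ei], False))
    arr = TrialArray(
        block=np.array([r[0] for r in rows]),
        trial=np.array([r[1] for r in rows]),
        reward_hi=np.array([r[2] for r in rows]),
        reward_lo=np.array([r[3] for r in rows]),
        effort_hi=np.array([r[4] for r in rows]),
        effort_lo=np.array([r[5] for r in rows]),
        is_catch=np.array([r[6] for r in rows]),
    )
    arr.validate()
    return arr


@dataclass(frozen=True)
class AttributionDesign:
    """Scenario structure of one causal-attribution session."""

    n_scenarios: int = 32
    n_positive: int = 16
    n_negative: int = 16
    n_blocks: int = 2
    n_response_options: int = 4

    def __post_init__(self):
        if self.n_positive + self.n_negative != self.n_scenarios:
            raise DesignError("valence counts must sum to n_scenarios")
        if self.n_response_options != 4:
            raise DesignError(
                "each trial offers the 2x2 internal/global grid exactly once"
            )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Ground truth for a simulated two-session randomized cohort.

    ``true_group_means`` maps parameter name to (session-1, session-2)
    means; ``true_intervention_effect`` is the additive shift applied to
    active-arm subjects' session-2 parameters; ``subject_sd`` the
    between-subject SD per parameter; ``cross_session_correlation`` the
    within-subject correlation of parameters across sessions (the quantity
    test-retest reliability estimates). For the attribution task,
    ``cross_trait_correlation`` couples the internal and global traits
    within a session (separable with the cross-session correlation, which
    keeps the implied covariance positive semidefinite).
    """

    n_subjects: int = 100
    allocation: tuple[int, int] = (1, 1)
    true_group_means: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    true_intervention_effect: Mapping[str, float] = field(
        default_factory=dict
    )
    subject_sd: Mapping[str, float] = field(default_factory=dict)
    cross_session_correlation: float = 0.7
    cross_trait_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise DesignError("need at least two subjects")
        for r, name in (
            (self.cross_session_correlation, "cross_session_correlation"),
            (self.cross_trait_correlation, "cross_trait_correlation"),
        ):
            if not -1.0 <= r <= 1.0:
                raise DesignError(f"{name} must lie in [-1, 1]")
        for k, sd in self.subject_sd.items():
            if sd < 0:
                raise DesignError(f"subject_sd[{k}] must be non-negative")

    def replace(self, **kw) -> "CohortConfig":
        return replace(self, **kw)


def default_reward_effort_cohort(**overrides) -> CohortConfig:
    """Study-scale defaults: N=100 randomized 1:1, reward sensitivity ~0.8
    per coin, effort sensitivity ~1.5 per unit fraction of maximal effort
    (higher-reward choice rates around 0.6-0.75), test-retest correlation
    0.7, no intervention effect unless specified."""
    base = dict(
        n_subjects=100,
        true_group_means={"rewSens": (0.8, 0.8), "effSens": (1.5, 1.5)},
        true_intervention_effect={"rewSens": 0.0, "effSens": 0.0},
        subject_sd={"rewSens": 0.4, "effSens": 0.4},
        cross_session_correlation=0.75,
    )
    base.update(overrides)
    return CohortConfig(**base)


ATTRIBUTION_PARAMS = ("internal_pos", "global_pos", "internal_neg",
                      "global_neg")


def default_attribution_cohort(**overrides) -> CohortConfig:
    """Defaults emulating the observed endorsement regime: internal
    attributions more likely for positive than negative events, around-even
    global rates, between-subject SD 1 on the latent (log-odds) scale."""
    base = dict(
        n_subjects=100,
        true_group_means={
            "internal_pos": (0.8, 0.8),
            "global_pos": (0.4, 0.4),
            "internal_neg": (-0.2, -0.2),
            "global_neg": (-0.2, -0.2),
        },
        true_intervention_effect={p: 0.0 for p in ATTRIBUTION_PARAMS},
        subject_sd={p: 1.0 for p in ATTRIBUTION_PARAMS},
        cross_session_correlation=0.7,
        cross_trait_correlation=0.3,
    )
    base.update(overrides)
    return CohortConfig(**base)


def _assign_arms(n: int, allocation: tuple[int, int],
                 rng: np.random.Generator) -> np.ndarray:
    """Randomized allocation honouring the ratio as closely as n allows."""
    a, c = allocation
    n_active = int(round(n * a / (a + c)))
    arms = np.array(["active"] * n_active + ["control"] * (n - n_active))
    return rng.permutation(arms)


def _session_pair(
    mean: tuple[float, float], sd: float, rho: float, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw (n, 2) correlated session parameters."""
    z = rng.standard_normal((n, 2))
    x2 = rho * z[:, 0] + np.sqrt(max(1.0 - rho**2, 0.0)) * z[:, 1]
    out = np.empty((n, 2))
    out[:, 0] = mean[0] + sd * z[:, 0]
    out[:, 1] = mean[1] + sd * x2
    return out


def _lognormal_rt(rng, size, median: float, sigma: float) -> np.ndarray:
    return np.exp(np.log(median) + sigma * rng.standard_normal(size))


def simulate_reward_effort_cohort(
    design: TrialArray,
    cohort: CohortConfig | None = None,
    rt_median: float = 1.2,
    rt_sigma: float = 0.4,
) -> pd.DataFrame:
    """Two-session trial-level choice data under the linear-value model.

    Subject parameters are drawn per parameter from a bivariate normal
    across sessions; active-arm session-2 parameters are shifted by the true
    intervention effect. Choices are Bernoulli with logit equal to the
    value difference between the higher- and lower-reward options.
    """
    cohort = cohort or default_reward_effort_cohort()
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n_subjects
    arms = _assign_arms(n, cohort.allocation, rng)
    active = arms == "active"

    params = {}
    for p in ("rewSens", "effSens"):
        vals = _session_pair(
            cohort.true_group_means[p],
            cohort.subject_sd[p],
            cohort.cross_session_correlation,
            n,
            rng,
        )
        vals[active, 1] += cohort.true_intervention_effect.get(p, 0.0)
        params[p] = vals

    dr = (design.reward_hi - design.reward_lo).astype(float)
    de = design.effort_hi - design.effort_lo
    frames = []
    for s in (1, 2):
        logit = (
            params["rewSens"][:, s - 1][:, None] * dr[None, :]
            - params["effSens"][:, s - 1][:, None] * de[None, :]
        )
        choice = (rng.random(logit.shape) < expit(logit)).astype(int)
        t = design.n_trials
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(np.arange(n), t),
                    "arm": np.repeat(arms, t),
                    "session": s,
                    "block": np.tile(design.block, n),
                    "trial": np.tile(design.trial, n),
                    "reward_hi": np.tile(design.reward_hi, n),
                    "reward_lo": np.tile(design.reward_lo, n),
                    "effort_hi": np.tile(design.effort_hi, n),
                    "effort_lo": np.tile(design.effort_lo, n),
                    "is_catch": np.tile(design.is_catch.astype(int), n),
                    "choice_hi": choice.reshape(-1),
                    "rt_s": _lognormal_rt(rng, n * t, rt_median, rt_sigma),
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.attrs["truth"] = {"params": params, "arms": arms, "cohort": cohort}
    return df


def simulate_attribution_cohort(
    design: AttributionDesign | None = None,
    cohort: CohortConfig | None = None,
    rt_median: float = 3.5,
    rt_sigma: float = 0.5,
) -> pd.DataFrame:
    """Two-session attribution responses from the latent-trait model.

    Per subject, session and valence, the internal and global latent traits
    follow a 4-dimensional normal whose correlation is the separable
    (Kronecker) product of the cross-session and cross-trait correlations.
    Each scenario yields two Bernoulli codes through the logistic link.
    """
    design = design or AttributionDesign()
    cohort = cohort or default_attribution_cohort()
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n_subjects
    arms = _assign_arms(n, cohort.allocation, rng)
    active = arms == "active"

    rs = cohort.cross_session_correlation
    rt_corr = cohort.cross_trait_correlation
    # order within a valence: (internal s1, global s1, internal s2, global s2)
    corr = np.kron(
        np.array([[1.0, rs], [rs, 1.0]]),
        np.array([[1.0, rt_corr], [rt_corr, 1.0]]),
    )
    L = corr_cholesky(corr)

    traits: dict[str, np.ndarray] = {}
    for val in ("pos", "neg"):
        sds = np.array(
            [
                cohort.subject_sd[f"internal_{val}"],
                cohort.subject_sd[f"global_{val}"],
            ]
            * 2
        )
        means = np.array(
            [
                cohort.true_group_means[f"internal_{val}"][0],
                cohort.true_group_means[f"global_{val}"][0],
                cohort.true_group_means[f"internal_{val}"][1],
                cohort.true_group_means[f"global_{val}"][1],
            ]
        )
        x = means + (rng.standard_normal((n, 4)) @ L.T) * sds
        x[active, 2] += cohort.true_intervention_effect.get(
            f"internal_{val}", 0.0
        )
        x[active, 3] += cohort.true_intervention_effect.get(
            f"global_{val}", 0.0
        )
        traits[val] = x  # columns: int s1, glob s1, int s2, glob s2

    n_per_val = {"pos": design.n_positive, "neg": design.n_negative}
    rows = []
    for s in (1, 2):
        for p in range(n):
            valences = np.array(
                ["pos"] * n_per_val["pos"] + ["neg"] * n_per_val["neg"]
            )
            valences = rng.permutation(valences)
            for t, val in enumerate(valences):
                col = 0 if s == 1 else 2
                th_int = traits[val][p, col]
                th_glob = traits[val][p, col + 1]
                rows.append(
                    (
                        p,
                        arms[p],
                        s,
                        t,
                        val,
                        int(rng.random() < expit(th_int)),
                        int(rng.random() < expit(th_glob)),
                        int(rng.integers(design.n_response_options)),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "arm",
            "session",
            "trial",
            "valence",
            "choice_internal",
            "choice_global",
            "option_position",
        ],
    )
    df["rt_s"] = _lognormal_rt(rng, len(df), rt_median, rt_sigma)
    df.attrs["truth"] = {"traits": traits, "arms": arms, "cohort": cohort}
    return df


# ---------------------------------------------------------------------------
# Item banks and graded responses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Item:
    item_id: str
    instrument: str
    trait: str  # 'A' amotivation, 'N' negative cognition
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self):
        if self.discrimination <= 0:
            raise DesignError(f"{self.item_id}: discrimination must be > 0")
        t = np.asarray(self.thresholds)
        if len(t) and np.any(np.diff(t) <= 0):
            raise DesignError(
                f"{self.item_id}: thresholds must be strictly increasing"
            )

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class ItemBank:
    items: tuple[Item, ...]

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def for_trait(self, trait: str) -> "ItemBank":
        return ItemBank(tuple(i for i in self.items if i.trait == trait))


def default_item_banks(seed: int = 7) -> ItemBank:
    """Synthetic item bank mirroring the published trait composition.

    Amotivation (A): six AMI behavioural-amotivation items (5 categories)
    plus the two PHQ9 anhedonia/fatigue items (4 categories). Negative
    cognition (N): eight DAS short-form items (4 categories) plus the two
    PHQ9 low-mood/failure items. Discriminations and thresholds are
    synthetic (real instrument text and calibrations are not shipped).
    """
    rng = np.random.default_rng(seed)
    items = []

    def make(instrument, trait, n_items, n_cat, start):
        for j in range(n_items):
            a = float(np.exp(rng.normal(0.4, 0.3)))
            center = rng.normal(0.0, 0.6)
            gaps = rng.uniform(0.6, 1.3, size=n_cat - 2)
            th = center + np.concatenate([[0.0], np.cumsum(gaps)])
            th -= th.mean()
            items.append(
                Item(
                    item_id=f"{instrument}_{start + j + 1}",
                    instrument=instrument,
                    trait=trait,
                    discrimination=a,
                    thresholds=tuple(np.round(th, 4)),
                )
            )

    make("AMI", "A", 6, 5, 0)
    make("PHQ9", "A", 2, 4, 0)
    make("DAS", "N", 8, 4, 0)
    make("PHQ9", "N", 2, 4, 2)
    return ItemBank(tuple(items))


def grm_category_probabilities(
    theta, discrimination: float, thresholds
) -> np.ndarray:
    """Graded-response category probabilities for one item.

    ``P(y >= k) = logistic(a*theta - kappa_k)``; category probabilities are
    differences of adjacent cumulative curves. Returns shape
    ``(*theta.shape, K)`` summing to one.
    """
    theta = np.asarray(theta, dtype=float)
    kappa = np.asarray(thresholds, dtype=float)
    if len(kappa) and np.any(np.diff(kappa) <= 0):
        raise DesignError("thresholds must be strictly increasing")
    cum = expit(discrimination * theta[..., None] - kappa)
    cum = np.concatenate(
        [np.ones((*cum.shape[:-1], 1)), cum, np.zeros((*cum.shape[:-1], 1))],
        axis=-1,
    )
    return -np.diff(cum, axis=-1)


def simulate_item_responses(
    traits: Mapping[str, np.ndarray],
    bank: ItemBank | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Ordinal item responses from the graded response model.

    ``traits`` maps trait label ('A', 'N') to per-subject latent values;
    responses are integers in [0, K-1].
    """
    bank = bank or default_item_banks()
    rng = np.random.default_rng(seed)
    missing = {i.trait for i in bank} - set(traits)
    if missing:
        raise SchemaError(f"no trait values supplied for {sorted(missing)}")
    frames = []
    for item in bank:
        th = np.asarray(traits[item.trait], dtype=float)
        probs = grm_category_probabilities(
            th, item.discrimination, item.thresholds
        )
        u = rng.random(len(th))
        resp = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.arange(len(th)),
                    "instrument": item.instrument,
                    "item_id": item.item_id,
                    "trait": item.trait,
                    "response": resp.astype(int),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_joint_cohort(
    design: TrialArray,
    cohort: CohortConfig | None = None,
    bank: ItemBank | None = None,
    beta_base: float = 0.0,
    beta_int: float = 0.0,
    target: str = "effSens",
    trait: str = "A",
    trait_correlation: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Reward-effort cohort whose target parameter is moderated by a latent
    symptom trait, plus matching graded item responses.

    The trait enters as in the joint moderation model: ``beta_base * theta``
    shifts the session-1 target parameter of every subject and ``beta_int *
    theta`` shifts the session-2 target parameter of active-arm subjects
    (on top of the group intervention effect).
    """
    cohort = cohort or default_reward_effort_cohort()
    bank = bank or default_item_banks()
    rng = np.random.default_rng(cohort.seed)
    n = cohort.n_subjects

    z = rng.standard_normal((n, 2))
    theta = {
        "A": z[:, 0],
        "N": trait_correlation * z[:, 0]
        + np.sqrt(1 - trait_correlation**2) * z[:, 1],
    }

    choice_df = simulate_reward_effort_cohort(design, cohort)
    truth = choice_df.attrs["truth"]
    params = truth["params"]
    active = truth["arms"] == "active"
    params[target][:, 0] += beta_base * theta[trait]
    params[target][active, 1] += beta_int * theta[trait][active]

    # regenerate choices under the moderated parameters
    dr = (design.reward_hi - design.reward_lo).astype(float)
    de = design.effort_hi - design.effort_lo
    for s in (1, 2):
        logit = (
            params["rewSens"][:, s - 1][:, None] * dr[None, :]
            - params["effSens"][:, s - 1][:, None] * de[None, :]
        )
        choice = (rng.random(logit.shape) < expit(logit)).astype(int)
        choice_df.loc[choice_df["session"] == s, "choice_hi"] = (
            choice.reshape(-1)
        )

    item_df = simulate_item_responses(
        theta, bank, seed=int(rng.integers(2**31))
    )
    truth.update(
        {
            "theta": theta,
            "beta_base": beta_base,
            "beta_int": beta_int,
            "target": target,
            "trait": trait,
        }
    )
    return choice_df, item_df, truth


# ---------------------------------------------------------------------------
# Exclusion rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionReport:
    excluded: dict[int, list[str]]
    n_before: int
    n_after: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"subject_id": sid, "reasons": ";".join(reasons)}
                for sid, reasons in sorted(self.excluded.items())
            ]
        )


def apply_exclusion_rules(
    data: pd.DataFrame, kind: str
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the published participant-level exclusion rules.

    reward-effort: a subject must choose the dominant option on at least one
    of the catch trials. attribution: median response time must exceed 2 s
    (strictly) and no response-option position may account for 75% or more
    of a subject's choices.
    """
    excluded: dict[int, list[str]] = {}
    if kind in ("reward-effort", "reward_effort"):
        needed = {"subject_id", "is_catch", "choice_hi"}
        if not needed <= set(data.columns):
            raise SchemaError(f"missing columns: {needed - set(data.columns)}")
        catch = data[data["is_catch"] == 1]
        correct = catch.groupby("subject_id")["choice_hi"].max()
        for sid, ok in correct.items():
            if ok == 0:
                excluded.setdefault(sid, []).append("catch")
    elif kind == "attribution":
        needed = {"subject_id", "rt_s", "option_position"}
        if not needed <= set(data.columns):
            raise SchemaError(f"missing columns: {needed - set(data.columns)}")
        for sid, grp in data.groupby("subject_id"):
            if grp["rt_s"].median() <= 2.0:
                excluded.setdefault(sid, []).append("rt")
            pos_frac = grp["option_position"].value_counts(normalize=True)
            if (pos_frac >= 0.75).any():
                excluded.setdefault(sid, []).append("position")
    else:
        raise ValueError(f"unknown task kind {kind!r}")

    keep = ~data["subject_id"].isin(excluded)
    filtered = data[keep].reset_index(drop=True)
    report = ExclusionReport(
        excluded=excluded,
        n_before=data["subject_id"].nunique(),
        n_after=filtered["subject_id"].nunique(),
    )
    return filtered, report
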