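"""Model-agnostic fit diagnostics: split-R-hat, pseudo-r2, posterior
predictive accuracy."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["rhat", "pseudo_r2", "FitMetrics"]


def _split_chains(chains: np.ndarray) -> np.ndarray:
    n_chains, n_draws = chains.shape
    half = n_draws // 2
    return np.concatenate(
        [chains[:, :half], chains[:, n_draws - half:]], axis=0
    )


def _classic_rhat(chains: np.ndarray) -> float:
    m, n = chains.shape
    chain_means = chains.mean(axis=1)
    b = n * np.var(chain_means, ddof=1)
    w = np.mean(np.var(chains, axis=1, ddof=1))
    if w == 0:
        return 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    flat = chains.reshape(-1)
    ranks = stats.rankdata(flat, method="average").reshape(chains.shape)
    s = flat.size
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (s - 2.0 * 3.0 / 8.0 + 1.0))


def rhat(chains) -> float:
    """Rank-normalized split potential-scale-reduction statistic.

    The maximum of the bulk (rank-normalized) and tail (rank-normalized
    folded) split-R-hat. ``chains`` is an (n_chains, n_draws) array or a
    list of equal-length 1-D arrays; at least two chains are required.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    if chains.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains")
    split = _split_chains(chains)
    bulk = _classic_rhat(_rank_normalize(split))
    folded = np.abs(split - np.median(split))
    tail = _classic_rhat(_rank_normalize(folded))
    return max(bulk, tail)


def pseudo_r2(L: float, n_trials: int, n_options: int = 2) -> float:
    """Likelihood-based variance explained relative to a chance model.

    ``1 - L/C`` with chance log likelihood ``C = n_trials * log(1/n_options)``
    (for two options, log(0.5) per trial). Zero at chance, one at perfect
    prediction.
    """
    if L > 0:
        raise ValueError("summed log likelihood must be <= 0")
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    c = n_trials * np.log(1.0 / n_options)
    return float(1.0 - L / c)


@dataclass(frozen=True)
class FitMetrics:
    """Goodness-of-fit bundle for one fitted model."""

    ppa_mean: float
    ppa_sd: float
    pseudo_r2: float
    L: float
    C: float

    def as_dict(self) -> dict:
        return {
            "ppa_mean": self.ppa_mean,
            "ppa_sd": self.ppa_sd,
            "pseudo_r2": self.pseudo_r2,
            "log_lik": self.L,
            "chance_log_lik": self.C,
        }
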