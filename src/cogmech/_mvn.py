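"""Correlation-matrix utilities for hierarchical multivariate-normal priors.

Correlation matrices are parameterized through canonical partial correlations
(the C-vine construction): ``n_pairs = d*(d-1)/2`` unconstrained reals map via
``tanh`` to partial correlations, which determine a valid correlation matrix.
Independent Beta(b, b) partials with ``b = eta + (d - 1 - i) / 2`` (1-based row
index i) induce the LKJ(eta) distribution on the matrix; for d = 2 and eta = 1
the single correlation is exactly uniform on [-1, 1].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "n_pairs",
    "pair_indices",
    "vine_beta_params",
    "partials_to_corr",
    "unconstrained_to_corr",
    "corr_log_prior",
    "sample_corr_unconstrained",
    "corr_cholesky",
]


def n_pairs(dim: int) -> int:
    return dim * (dim - 1) // 2


def pair_indices(dim: int) -> list[tuple[int, int]]:
    """Row-major (i, j), i < j, ordering of the off-diagonal pairs."""
    return [(i, j) for i in range(dim - 1) for j in range(i + 1, dim)]


def vine_beta_params(dim: int, eta: float = 1.0) -> np.ndarray:
    """Beta(b, b) shape for each canonical partial correlation.

    The shape depends only on the first index of the pair: b_i = eta
    + (dim - 1 - i)/2 with i 1-based, so lower rows get flatter Betas.
    """
    return np.array(
        [eta + (dim - 2 - i) / 2.0 for i, _ in pair_indices(dim)], dtype=float
    )


def partials_to_corr(partials: np.ndarray, dim: int) -> np.ndarray:
    """Build the correlation matrix from canonical partial correlations."""
    partials = np.asarray(partials, dtype=float)
    if partials.shape != (n_pairs(dim),):
        raise ValueError(f"expected {n_pairs(dim)} partials for dim={dim}")
    P = np.zeros((dim, dim))
    for (i, j), p in zip(pair_indices(dim), partials):
        P[i, j] = p
    R = np.eye(dim)
    for i in range(dim - 1):
        for j in range(i + 1, dim):
            p = P[i, j]
            for k in range(i - 1, -1, -1):
                p = p * np.sqrt((1.0 - P[k, j] ** 2) * (1.0 - P[k, i] ** 2)) + (
                    P[k, i] * P[k, j]
                )
            R[i, j] = R[j, i] = p
    return R


def unconstrained_to_corr(c: np.ndarray, dim: int) -> np.ndarray:
    return partials_to_corr(np.tanh(np.asarray(c, dtype=float)), dim)


def corr_log_prior(c: np.ndarray, dim: int, eta: float = 1.0) -> float:
    """Log density (up to a constant) of the LKJ(eta) prior on the
    unconstrained partial-correlation scale, tanh Jacobian included."""
    c = np.asarray(c, dtype=float)
    b = vine_beta_params(dim, eta)
    # Beta(b,b) density on p = tanh(c) contributes (b-1)*log(1-p^2); the
    # tanh change of variables contributes log(1-p^2); total b*log(1-p^2).
    # log(1 - tanh(c)^2) = log(4) - 2*log(exp(c) + exp(-c)), computed stably.
    log1m_p2 = np.log(4.0) - 2.0 * np.logaddexp(c, -c)
    return float(np.sum(b * log1m_p2))


def sample_corr_unconstrained(
    rng: np.random.Generator, dim: int, eta: float = 1.0
) -> np.ndarray:
    """Draw unconstrained partials whose tanh follows the LKJ(eta) vine."""
    b = vine_beta_params(dim, eta)
    p = 2.0 * rng.beta(b, b) - 1.0
    p = np.clip(p, -0.999999, 0.999999)
    return np.arctanh(p)


def corr_cholesky(R: np.ndarray, jitter: float = 1e-10) -> np.ndarray:
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        d = R.shape[0]
        return np.linalg.cholesky(R + jitter * np.eye(d))
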