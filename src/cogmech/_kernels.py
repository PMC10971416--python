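"""Numerical hot loops, JIT-compiled when numba is available.

The Bernoulli row log likelihood — sum over trials of
``-log(1 + exp(-sign * logit))`` with zero-sign entries masked out — is the
single dominant cost of every model fit here; the fused kernel avoids the
large temporaries the numpy expression allocates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bernoulli_row_loglik"]


def _bern_rows(logit, sign):
    n, t = logit.shape
    out = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(t):
            sg = sign[i, j]
            if sg != 0.0:
                x = -sg * logit[i, j]
                if x > 0.0:
                    s -= x + np.log1p(np.exp(-x))
                else:
                    s -= np.log1p(np.exp(x))
        out[i] = s
    return out


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    bernoulli_row_loglik = njit(cache=True, fastmath=False)(_bern_rows)
except Exception:  # pragma: no cover
    def bernoulli_row_loglik(logit, sign):
        ll = -np.logaddexp(0.0, -sign * logit)
        return np.where(sign != 0.0, ll, 0.0).sum(axis=1)
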