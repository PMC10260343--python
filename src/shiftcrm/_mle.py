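"""JIT-compiled likelihood kernels for the one-parameter power (empiric) CRM.

The model is p_ij = q_ij^{exp(a)} with skeleton q and a real parameter a.
Data enter as per-cell counts (n treated, x DLTs) over grid cells with at
least one patient, so a likelihood evaluation is O(#occupied cells)
regardless of sample size. The MLE of a is found by golden-section search on
a bounded interval; the log-likelihood is concave in exp(a), hence unimodal
in a, so golden section converges to the global interior maximum (or to the
boundary when the data push the estimate there).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


@njit(cache=False)
def loglik_counts(lam: float, logq: np.ndarray, n: np.ndarray, x: np.ndarray) -> float:
    """Log-likelihood at power lam = exp(a) for per-cell counts.

    logq are log skeleton values of the occupied cells; n and x the
    corresponding patient and DLT counts.
    """
    ll = 0.0
    for i in range(logq.shape[0]):
        s = lam * logq[i]  # log of q^lam, always < 0
        ll += x[i] * s
        m = n[i] - x[i]
        if m > 0:
            ll += m * math.log1p(-math.exp(s))
    return ll


@njit(cache=False)
def mle_power(
    logq: np.ndarray,
    n: np.ndarray,
    x: np.ndarray,
    a_lo: float,
    a_hi: float,
    tol: float,
) -> tuple[float, float]:
    """Golden-section maximizer of the log-likelihood over a in [a_lo, a_hi].

    Returns (a_hat, loglik at a_hat).
    """
    a, b = a_lo, a_hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc = loglik_counts(math.exp(c), logq, n, x)
    fd = loglik_counts(math.exp(d), logq, n, x)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = loglik_counts(math.exp(c), logq, n, x)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = loglik_counts(math.exp(d), logq, n, x)
    a_hat = 0.5 * (a + b)
    return a_hat, loglik_counts(math.exp(a_hat), logq, n, x)
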