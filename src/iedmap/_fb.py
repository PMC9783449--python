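"""Scaled forward-backward recursions (numba-compiled inner loops)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def _fb_core(B, A, pi):
    """Scaled alpha/beta recursions.

    ``B``: (T, K) positive observation weights (already max-shifted),
    ``A``: (K, K) transition weights, ``pi``: (K,) initial weights.
    Returns gamma (T, K), xi_sums (K, K), log_norm = sum(log c_t).
    """
    T, K = B.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)

    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * B[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s

    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * B[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += A[k, j] * B[t + 1, j] * beta[t + 1, j]
            beta[t, k] = acc / c[t + 1]

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    xi = np.zeros((K, K))
    for t in range(T - 1):
        for j in range(K):
            for k in range(K):
                xi[j, k] += alpha[t, j] * A[j, k] * B[t + 1, k] * beta[t + 1, k] / c[t + 1]

    log_norm = 0.0
    for t in range(T):
        log_norm += np.log(c[t])
    return gamma, xi, log_norm
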