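"""Numba kernels for hidden-Markov inference on displacement sequences.

Everything runs in log space; T is the number of displacements and K the
number of hidden states (K <= 3 in practice, so the inner loops are tiny).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(fastmath=False)
def _logsumexp2(a):  # 1-D helper
    m = np.max(a)
    if m == -np.inf:
        return -np.inf
    s = 0.0
    for i in range(a.shape[0]):
        s += np.exp(a[i] - m)
    return m + np.log(s)


@njit(fastmath=False)
def e_step(log_pi, log_A, log_b):
    """Scaled (log-space) forward-backward pass.

    Returns (loglik, gamma, xi_sum) where gamma[t, k] are state posteriors per
    displacement and xi_sum[i, j] the expected transition counts.
    """
    T, K = log_b.shape
    log_alpha = np.empty((T, K))
    log_beta = np.empty((T, K))
    work = np.empty(K)

    for k in range(K):
        log_alpha[0, k] = log_pi[k] + log_b[0, k]
    for t in range(1, T):
        for k in range(K):
            for j in range(K):
                work[j] = log_alpha[t - 1, j] + log_A[j, k]
            log_alpha[t, k] = _logsumexp2(work) + log_b[t, k]

    loglik = _logsumexp2(log_alpha[T - 1])

    for k in range(K):
        log_beta[T - 1, k] = 0.0
    for t in range(T - 2, -1, -1):
        for k in range(K):
            for j in range(K):
                work[j] = log_A[k, j] + log_b[t + 1, j] + log_beta[t + 1, j]
            log_beta[t, k] = _logsumexp2(work)

    gamma = np.empty((T, K))
    for t in range(T):
        for k in range(K):
            work[k] = log_alpha[t, k] + log_beta[t, k]
        norm = _logsumexp2(work)
        for k in range(K):
            gamma[t, k] = np.exp(work[k] - norm)

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += np.exp(
                    log_alpha[t, i] + log_A[i, j] + log_b[t + 1, j]
                    + log_beta[t + 1, j] - loglik
                )
    return loglik, gamma, xi_sum


@njit(fastmath=False)
def viterbi(log_pi, log_A, log_b):
    """Most probable state path; ties resolve to the lowest state index."""
    T, K = log_b.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + log_b[0, k]
    for t in range(1, T):
        for k in range(K):
            best, arg = -np.inf, 0
            for j in range(K):
                cand = delta[t - 1, j] + log_A[j, k]
                if cand > best:  # strict: first (lowest) index wins ties
                    best, arg = cand, j
            delta[t, k] = best + log_b[t, k]
            psi[t, k] = arg
    path = np.zeros(T, dtype=np.int64)
    best, arg = -np.inf, 0
    for k in range(K):
        if delta[T - 1, k] > best:
            best, arg = delta[T - 1, k], k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
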