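"""Numba inner loops: scaled forward-backward, Viterbi, chain samplers.

All recursions normalize per time step, which is algebraically the same as
running in log space for the forward/backward quantities while keeping the
inner loops branch-free. Viterbi scores are accumulated in log space
directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward_scaled(b, transition, initial):
    """Posterior state marginals for one run.

    Parameters
    ----------
    b : (T, K) nonnegative likelihoods, already rescaled per row (any
        positive per-row factor cancels except in the returned log constant,
        which the caller adds back).
    transition, initial : row-stochastic (K, K) and (K,) parameters.

    Returns
    -------
    gamma : (T, K) posteriors, rows sum to 1.
    xi : (T-1, K, K) pairwise posteriors, each slice sums to 1.
    log_c : sum of per-step scaling logs = log evidence of the rescaled b.
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    c = np.empty(T)

    for k in range(K):
        alpha[0, k] = initial[k] * b[0, k]
    s = 0.0
    for k in range(K):
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            a = 0.0
            for j in range(K):
                a += alpha[t - 1, j] * transition[j, k]
            a *= b[t, k]
            alpha[t, k] = a
            s += a
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for j in range(K):
            a = 0.0
            for k in range(K):
                a += transition[j, k] * b[t + 1, k] * beta[t + 1, k]
            beta[t, j] = a / c[t + 1]

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            g = alpha[t, k] * beta[t, k]
            gamma[t, k] = g
            s += g
        for k in range(K):
            gamma[t, k] /= s

    xi = np.empty((T - 1, K, K))
    for t in range(T - 1):
        s = 0.0
        for j in range(K):
            for k in range(K):
                v = alpha[t, j] * transition[j, k] * b[t + 1, k] * beta[t + 1, k]
                xi[t, j, k] = v
                s += v
        for j in range(K):
            for k in range(K):
                xi[t, j, k] /= s

    log_c = 0.0
    for t in range(T):
        log_c += np.log(c[t])
    return gamma, xi, log_c


@njit(cache=True)
def viterbi_path(log_b, log_transition, log_initial):
    """Most likely state sequence; ties broken toward the lower state index.

    Returns (path, best_log_joint).
    """
    T, K = log_b.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_initial[k] + log_b[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + log_transition[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + log_transition[j, k]
                if v > best:          # strict: first (lowest) index wins ties
                    best = v
                    arg = j
            delta[t, k] = best + log_b[t, k]
            psi[t, k] = arg
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path = np.empty(T, dtype=np.int64)
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


@njit(cache=True)
def sample_chain(cum_transition, cum_initial, uniforms):
    """Sample a Markov chain given cumulative-sum rows and uniform draws."""
    T = uniforms.shape[0]
    K = cum_initial.shape[0]
    path = np.empty(T, dtype=np.int64)
    u = uniforms[0]
    k = 0
    while k < K - 1 and u > cum_initial[k]:
        k += 1
    path[0] = k
    for t in range(1, T):
        u = uniforms[t]
        row = cum_transition[path[t - 1]]
        k = 0
        while k < K - 1 and u > row[k]:
            k += 1
        path[t] = k
    return path


@njit(cache=True)
def sample_chain_mixture(stationary_course, persistence, uniforms, u_switch):
    """Sample a chain with time-varying mixture transitions.

    At each step the chain stays with probability ``persistence`` and
    otherwise redraws from the step's target distribution
    ``stationary_course[t]`` (rows sum to 1). Supports slow occupancy
    ramps (e.g. a post-eye-closure occupancy spike decaying over minutes).
    """
    T, K = stationary_course.shape
    path = np.empty(T, dtype=np.int64)
    u = uniforms[0]
    acc = 0.0
    k = 0
    for j in range(K):
        acc += stationary_course[0, j]
        if u <= acc:
            k = j
            break
        k = j
    path[0] = k
    for t in range(1, T):
        if u_switch[t] < persistence:
            path[t] = path[t - 1]
        else:
            u = uniforms[t]
            acc = 0.0
            k = K - 1
            for j in range(K):
                acc += stationary_course[t, j]
                if u <= acc:
                    k = j
                    break
            path[t] = k
    return path


@njit(cache=True)
def ar1_noise(white, rho):
    """Turn white noise into an AR(1) process with coefficient rho."""
    T = white.shape[0]
    out = np.empty_like(white)
    scale = np.sqrt(1.0 - rho * rho)
    out[0] = white[0]
    for t in range(1, T):
        out[t] = rho * out[t - 1] + scale * white[t]
    return out
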