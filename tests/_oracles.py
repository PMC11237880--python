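"""Brute-force oracles: exhaustive enumeration over all state sequences.

Independent of the package's recursions - every path's probability is
accumulated explicitly, so these are exact (up to float rounding) for
small K**T.
"""

import itertools

import numpy as np


def enumerate_posteriors(log_b, transition, initial):
    """(gamma, xi, log_evidence) by summing over all K**T sequences."""
    T, K = log_b.shape
    gamma = np.zeros((T, K))
    xi = np.zeros((max(T - 1, 0), K, K))
    total = 0.0
    for seq in itertools.product(range(K), repeat=T):
        p = initial[seq[0]] * np.exp(log_b[0, seq[0]])
        for t in range(1, T):
            p *= transition[seq[t - 1], seq[t]] * np.exp(log_b[t, seq[t]])
        total += p
        for t in range(T):
            gamma[t, seq[t]] += p
        for t in range(T - 1):
            xi[t, seq[t], seq[t + 1]] += p
    return gamma / total, xi / total, np.log(total)


def enumerate_viterbi(log_b, log_transition, log_initial):
    """(best path, best log joint); ties resolved toward the
    lexicographically smallest sequence (lowest state indices first)."""
    T, K = log_b.shape
    best_seq, best_score = None, -np.inf
    for seq in itertools.product(range(K), repeat=T):
        s = log_initial[seq[0]] + log_b[0, seq[0]]
        for t in range(1, T):
            s += log_transition[seq[t - 1], seq[t]] + log_b[t, seq[t]]
        if s > best_score:
            best_score, best_seq = s, seq
    return np.array(best_seq), best_score
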