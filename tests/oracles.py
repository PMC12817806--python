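"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's vectorized code paths: the particle
marginal is computed by exhaustive enumeration over the assemblage assignment
and every read's contamination flag, and the one-sided co-occurrence p-value
by summing the hypergeometric mass over all more-extreme 2x2 tables.
"""

from itertools import product

import numpy as np
from scipy.special import comb


def particle_log_marginal_enum(reads, beta, theta, G_t, pi_G):
    """Exhaustive sum over (z, per-read contamination flags)."""
    reads = np.asarray(reads, dtype=int)
    theta = np.atleast_2d(theta)
    otus = np.repeat(np.arange(len(reads)), reads)
    n = len(otus)
    total = 0.0
    for k in range(theta.shape[0]):
        for flags in product([0, 1], repeat=n):
            p = beta[k]
            for o, a in zip(otus, flags):
                p *= (pi_G * G_t[o]) if a else ((1 - pi_G) * theta[k, o])
            total += p
    return np.log(total) if total > 0 else -np.inf


def fisher_greater_enum(a, n_i, n_j, N):
    """P(X >= a) for X hypergeometric: co-occurrences of two OTUs with
    prevalences n_i, n_j among N particles, by direct summation."""
    lo = max(0, n_i + n_j - N)
    hi = min(n_i, n_j)
    denom = comb(N, n_j, exact=True)
    total = 0
    for x in range(a, hi + 1):
        total += comb(n_i, x, exact=True) * comb(N - n_i, n_j - x, exact=True)
    return total / denom
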