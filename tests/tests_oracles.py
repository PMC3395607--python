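"""Independent oracle implementations shared by the acceptance tests.

These are deliberately naive (explicit loops, exact enumeration) and must
stay independent of the package code paths they check.
"""

import numpy as np
from scipy.special import comb

BASES = ("A", "C", "G", "T")


def oracle_base_lik(b, q, h):
    e = 10 ** (-q / 10)
    return 1 - e if b == h else e / 3


def oracle_fragment_likelihood(frag, alleles, p):
    """Exhaustive enumeration over (haplotype, fragment-base) states."""
    total = 0.0
    for h in alleles:
        for f in BASES:
            pf = (1 - p) if f == h else p / 3
            term = pf
            for b, q in frag.observations:
                term *= oracle_base_lik(b, q, f)
            total += 0.5 * term
    return total


def loop_weighted_moments_oracle(points, resp, g):
    """Responsibility-weighted mean / covariance by explicit loops."""
    w = sum(resp[n][g] for n in range(len(points)))
    mean = np.zeros(2)
    for n, pt in enumerate(points):
        mean += resp[n][g] * np.asarray(pt)
    mean /= w
    cov = np.zeros((2, 2))
    for n, pt in enumerate(points):
        d = np.asarray(pt) - mean
        cov += resp[n][g] * np.outer(d, d)
    return mean, cov / w


def hypergeom_fisher_oracle(table):
    """Two-sided Fisher exact p by explicit hypergeometric enumeration."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2

    def prob(x):
        return (
            comb(col1, x, exact=True)
            * comb(n - col1, row1 - x, exact=True)
            / comb(n, row1, exact=True)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, col1 - row2), min(col1, row1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total
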