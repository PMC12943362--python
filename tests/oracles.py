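"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (enumeration, double loops) kept apart
from the library code paths they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def bh_stepup_bruteforce(pvals):
    """Literal step-up definition: q_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


def mwu_exact_p_enumeration(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    observed = u_stat(x, y)
    mean_u = n1 * n2 / 2.0
    dev = abs(observed - mean_u)
    total = comb(n1 + n2, n1)
    count = 0
    idx = range(n1 + n2)
    for chosen in combinations(idx, n1):
        xs = [pooled[i] for i in chosen]
        ys = [pooled[i] for i in idx if i not in chosen]
        if abs(u_stat(xs, ys) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


def auc_pair_counting(pos, neg):
    """AUC by explicit concordant-pair counting (ties one half)."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def cliffs_delta_enumeration(x, y):
    """Cliff's delta by explicit pair enumeration."""
    net = sum(1 if a > b else -1 if a < b else 0 for a in x for b in y)
    return net / (len(x) * len(y))


def phi_from_indicators(x_binary, y_binary):
    """Phi of two binary vectors is their Pearson correlation."""
    return float(np.corrcoef(np.asarray(x_binary, float),
                             np.asarray(y_binary, float))[0, 1])


def hypergeom_tail_enumeration(k, M, K, N):
    """P(overlap >= k) drawing N from a background of M with K marked."""
    total = comb(M, N)
    return sum(comb(K, j) * comb(M - K, N - j)
               for j in range(k, min(K, N) + 1)) / total
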