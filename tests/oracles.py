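"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the textbook definition, deliberately not
sharing code paths with the package.
"""

from __future__ import annotations

import math

import numpy as np


def bh_stepup(p):
    """O(m^2) Benjamini-Hochberg step-up straight from the definition.

    adjusted(i) = min over all j with p_j >= p_i of m * p_j / rank(p_j),
    capped at 1, where rank(p_j) is the 1-based position of p_j in the
    sorted order (maximal rank among ties).
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    ranks = np.array([int((p <= v).sum()) for v in p])  # max rank among ties
    out = np.empty(m)
    for i in range(m):
        candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
        out[i] = min(1.0, min(candidates))
    return out


def fisher_two_sided(a, b, c, d, rel_tol=1e-7):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums P(x) over every table with the observed margins whose probability is
    no greater than the observed table's (within a relative float tolerance).
    """
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + rel_tol))


def pooled_t(group_a, group_b):
    """Textbook pooled two-sample t statistic."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    return (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


def pearson_r(x, y):
    """Covariance-ratio Pearson correlation from the definition."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def entropy_rate_bruteforce(graph, expression):
    """Entropy rate from first principles with explicit loops.

    Builds p_ij by mass action, local entropies by summation, and the
    stationary distribution by solving the left-eigenproblem as a linear
    system (P^T - I stacked with the normalisation row) — a route independent
    of both the closed form and the eigen decomposition used by the package.
    """
    nodes = sorted(graph.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    p = np.zeros((n, n))
    for u in nodes:
        denom = sum(expression[w] for w in graph.neighbors(u))
        for w in graph.neighbors(u):
            p[idx[u], idx[w]] = expression[w] / denom
    s = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if p[i, j] > 0:
                s[i] -= p[i, j] * math.log(p[i, j])
    a = np.vstack([p.T - np.eye(n), np.ones(n)])
    rhs = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(a, rhs, rcond=None)
    return float(pi @ s), pi, s
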