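"""Independent brute-force oracles used to pin expected values.

These are deliberately naive implementations written straight from the
defining formulas, kept separate from the package code paths they check.
"""

import itertools

import numpy as np
from scipy import stats as sps


def kruskal_h_bruteforce(groups):
    """H from the rank-sum definition with the tie correction factor."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)  # mid-ranks
    n = len(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[bounds[i]:bounds[i + 1]].sum() ** 2 / len(g)
        for i, g in enumerate(groups)
    ) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


def bh_adjust_bruteforce(p):
    """Benjamini-Hochberg step-up from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def mann_whitney_p_exhaustive(x, y):
    """Two-sided p by exhaustive enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)

    def u_min(idx):
        r1 = ranks[list(idx)].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        return min(u1, n1 * len(y) - u1)

    observed = u_min(range(n1))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if u_min(idx) <= observed + 1e-12:
            count += 1
    return count / total


def chi2_bruteforce(table):
    """Pearson chi-squared straight from sum((O-E)^2 / E)."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    return ((table - expected) ** 2 / expected).sum()
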