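"""Independent definitional oracles used to cross-check the implementation."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def holm_oracle(pvals, alpha=0.05):
    """Holm step-down from its definition: sort ascending, reject while
    p(i) <= alpha/(m-i+1), stop at the first failure."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    return reject


def bh_oracle(pvals, alpha=0.05):
    """Benjamini-Hochberg step-up from its definition: largest k with
    p(k) <= k*alpha/m; reject the k smallest."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * alpha / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def mw_permutation_pvalue(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Valid for tie-free pooled data: p = fraction of label assignments
    whose U statistic is at least as extreme (two-sided around mn/2) as
    the observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    m, n = len(x), len(y)
    mid = m * n / 2.0

    def u_stat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b)

    obs_dev = abs(u_stat(x, y) - mid)
    idx = range(m + n)
    count = total = 0
    for group_x in combinations(idx, m):
        xs = pooled[list(group_x)]
        ys = pooled[[i for i in idx if i not in set(group_x)]]
        total += 1
        if abs(u_stat(xs, ys) - mid) >= obs_dev - 1e-12:
            count += 1
    return count / total
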