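"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: Newton iteration on
the raw binomial log-likelihood, textbook step-down/step-up adjustment loops,
exhaustive rank enumeration and union-find transitive closure.
"""

from itertools import combinations

import numpy as np
from scipy import stats


def newton_logistic_mle(observations):
    """Grouped-logistic MLE by Newton iteration from zero.

    observations: iterable of (k, n, x) with x the treatment indicator.
    Returns (beta0, beta1, se_beta1).
    """
    obs = np.asarray(observations, dtype=float)
    k, n, x = obs[:, 0], obs[:, 1], obs[:, 2]
    design = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    for _ in range(100):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = design.T @ (n * mu - k)
        w = n * mu * (1.0 - mu)
        hess = design.T @ (design * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = n * mu * (1.0 - mu)
    cov = np.linalg.inv(design.T @ (design * w[:, None]))
    return beta[0], beta[1], float(np.sqrt(cov[1, 1]))


def holm_oracle(p):
    """Textbook step-down Holm adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def bh_oracle(p):
    """Textbook step-up Benjamini-Hochberg adjustment."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, m * p[idx] / (rank + 1))
        adjusted[idx] = running
    return adjusted


def exact_rank_sum_p(a, b):
    """Exhaustive two-sided rank-sum p-value for tiny samples (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    observed = ranks[:len(a)].sum()
    n = len(pooled)
    sums = np.asarray([sum(ranks[list(c)])
                       for c in combinations(range(n), len(a))])
    mean = sums.mean()
    extreme = np.abs(sums - mean) >= abs(observed - mean) - 1e-12
    return extreme.mean()


def union_find_oracle(starts, window):
    """O(n^2) transitive closure over the pairwise within-window relation."""
    n = len(starts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(starts[i] - starts[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())
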