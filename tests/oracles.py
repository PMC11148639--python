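"""Brute-force oracles, kept independent of the package implementation."""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def ranksum_p_enumeration(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p by enumerating all rank splits.

    Assumes no ties. The statistic is the rank sum of group a; the p-value
    is the fraction of C(n, na) assignments with a rank sum at least as
    extreme (two-sided, by distance from the mean rank sum).
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires tie-free data"
    ranks = pooled.argsort().argsort() + 1
    obs = ranks[: len(a)].sum()
    n, na = len(pooled), len(a)
    mean = na * (n + 1) / 2
    count = 0
    for idx in combinations(range(n), na):
        stat = sum(sorted(range(1, n + 1))[i] for i in idx)
        if abs(stat - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / comb(n, na)


def fisher_p_enumeration(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration.

    Sums the probabilities of all tables with the same margins whose
    probability does not exceed that of the observed table.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def bh_stepup(pvals) -> np.ndarray:
    """Benjamini-Hochberg q-values by the step-up formula."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def mean_block_correlations(values, membership) -> tuple[float, float]:
    """Mean within-module and between-module Spearman, by direct ranking."""
    from scipy.stats import rankdata

    ranked = np.apply_along_axis(rankdata, 0, np.asarray(values, float))
    corr = np.corrcoef(ranked.T)
    membership = np.asarray(membership)
    within, between = [], []
    for i in range(len(membership)):
        for j in range(i + 1, len(membership)):
            if membership[i] == membership[j] and membership[i] != -1:
                within.append(corr[i, j])
            elif membership[i] != membership[j]:
                between.append(corr[i, j])
    return float(np.mean(within)), float(np.mean(between))


def silhouette_brute(dist, labels) -> float:
    """Mean silhouette from its definition; singleton clusters score 0."""
    dist = np.asarray(dist, float)
    labels = np.asarray(labels)
    n = len(labels)
    scores = np.zeros(n)
    for i in range(n):
        same = (labels == labels[i]) & (np.arange(n) != i)
        if same.sum() == 0:
            scores[i] = 0.0
            continue
        a = dist[i, same].mean()
        b = min(
            dist[i, labels == other].mean()
            for other in np.unique(labels)
            if other != labels[i]
        )
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def gini_simpson_direct(counts) -> float:
    p = np.asarray(counts, float)
    p = p / p.sum()
    return float(1.0 - (p**2).sum())


def morisita_horn_direct(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    big_x, big_y = x.sum(), y.sum()
    dx, dy = (x**2).sum() / big_x**2, (y**2).sum() / big_y**2
    return float(2 * (x * y).sum() / ((dx + dy) * big_x * big_y))
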