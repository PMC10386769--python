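"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a statistic by the most direct method available
(full enumeration, plain-loop running sums, exact combinatorics) and is
deliberately kept independent of the implementation paths it checks.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps


def wilcoxon_two_sided_by_enumeration(values_a, values_b) -> float:
    """Exact two-sided rank-sum p by enumerating all label assignments."""
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n_a = a.size
    observed = ranks[:n_a].sum()
    sums = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(pooled.size), n_a)
    ]
    sums = np.asarray(sums)
    lower = np.mean(sums <= observed + 1e-9)
    upper = np.mean(sums >= observed - 1e-9)
    return min(1.0, 2.0 * min(lower, upper))


def enrichment_score_bruteforce(genes, stats, members, weight) -> float:
    """Plain-loop weighted running-sum ES."""
    members = set(members)
    n = len(genes)
    n_hit = sum(g in members for g in genes)
    norm = sum(abs(s) ** weight for g, s in zip(genes, stats) if g in members)
    running = 0.0
    walk = []
    for g, s in zip(genes, stats):
        if g in members:
            running += (abs(s) ** weight / norm) if norm > 0 else 1.0 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        walk.append(running)
    hi, lo = max(walk), min(walk)
    if hi + lo > 1e-9:
        return hi
    if hi + lo < -1e-9:
        return lo
    return lo if sum(walk) < -1e-9 else hi


def hypergeom_upper_tail(k, universe_size, set_size, query_size) -> float:
    """P(X >= k) by exact combinatorial summation."""
    total = math.comb(universe_size, query_size)
    acc = 0
    for i in range(k, min(set_size, query_size) + 1):
        acc += math.comb(set_size, i) * math.comb(
            universe_size - set_size, query_size - i
        )
    return acc / total


def pca_coordinates_by_covariance(x, k):
    """PCA scores via eigendecomposition of the feature covariance."""
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    return xc @ eigvecs[:, order[:k]]
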