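"""Independent brute-force oracles used by the test suite.

Everything here is written from first principles (neighborhood graphs,
explicit pmf summation, exhaustive pairwise checks) and never calls the
package code paths it is used to verify.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def brute_pairwise_euclidean(X: np.ndarray) -> np.ndarray:
    """Distances between columns, by the definition."""
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = math.sqrt(float(((X[:, i] - X[:, j]) ** 2).sum()))
    return D


def brute_pairwise_correlation(X: np.ndarray) -> np.ndarray:
    """1 - Pearson r between columns, by the formula."""
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            D[i, j] = 1.0 - brute_pearson(X[:, i], X[:, j])
    return np.clip(D, 0.0, None)


def brute_pearson(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float((xc**2).sum())) * math.sqrt(float((yc**2).sum()))
    if denom == 0:
        return 0.0
    return float((xc * yc).sum() / denom)


def brute_dbscan(D: np.ndarray, eps: float, min_samples: int):
    """DBSCAN by definition on a precomputed distance matrix.

    Core point: >= min_samples points (itself included) within eps.
    Clusters: connected components of core points under eps-adjacency, plus
    border points attached to the first cluster that reaches them in scan
    order. Returns labels with -1 for noise (sklearn convention).
    """
    n = D.shape[0]
    neighbors = [set(np.flatnonzero(D[i] <= eps)) for i in range(n)]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = np.full(n, -1, dtype=int)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            p = queue.pop(0)
            for q in sorted(neighbors[p]):
                if labels[q] == -1:
                    labels[q] = cluster
                    if core[q]:
                        queue.append(q)
        cluster += 1
    return labels


def brute_cover(fmin: float, fmax: float, n: int, g: float):
    """Uniform-length, uniform-overlap intervals from the closed form."""
    L = (fmax - fmin) / (n - (n - 1) * g)
    return [(fmin + j * (1 - g) * L, fmin + j * (1 - g) * L + L) for j in range(n)]


def brute_mapper(ids, X: np.ndarray, f: np.ndarray, n: int, g: float,
                 eps: float, min_samples: int, metric: str = "euclidean"):
    """Full Mapper composition, independently: cover -> DBSCAN -> nerve.

    Returns (node member frozensets in construction order, set of
    (i, j, weight) edges over those node indices, noise sample set).
    """
    intervals = brute_cover(float(f.min()), float(f.max()), n, g)
    intervals[-1] = (intervals[-1][0], float(f.max()))
    nodes = []
    noise: set = set()
    for lo, hi in intervals:
        idx = [k for k in range(len(ids)) if lo <= f[k] <= hi]
        if not idx:
            continue
        sub = X[:, idx]
        if metric == "euclidean":
            D = brute_pairwise_euclidean(sub)
        else:
            D = brute_pairwise_correlation(sub)
        labels = brute_dbscan(D, eps, min_samples)
        for lab in sorted(set(labels) - {-1}):
            nodes.append(frozenset(ids[idx[k]] for k in range(len(idx)) if labels[k] == lab))
        noise.update(ids[idx[k]] for k in range(len(idx)) if labels[k] == -1)
    edges = set()
    for a, b in itertools.combinations(range(len(nodes)), 2):
        shared = nodes[a] & nodes[b]
        if shared:
            edges.add((a, b, len(shared)))
    return nodes, edges, noise


def brute_binomial_upper(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), by direct pmf summation."""
    total = 0.0
    for i in range(n, k - 1, -1):  # smallest terms first
        total += math.comb(n, i) * (p0**i) * ((1 - p0) ** (n - i))
    return min(total, 1.0)


def brute_binomial_lower(k: int, n: int, p0: float) -> float:
    total = 0.0
    for i in range(0, k + 1):
        total += math.comb(n, i) * (p0**i) * ((1 - p0) ** (n - i))
    return min(total, 1.0)


def brute_hypergeom_upper(k: int, M: int, K: int, n: int) -> float:
    """P(overlap >= k) drawing n from M with K marked — exact rationals."""
    total = Fraction(0)
    denom = math.comb(M, n)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(M - K, n - i), denom)
    return float(min(total, Fraction(1)))
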