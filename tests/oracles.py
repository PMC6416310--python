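"""Independent brute-force reference implementations used only by tests.

Each oracle is deliberately naive (explicit loops, exact integer
arithmetic) and shares no code with the package paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


def hypergeom_tail_exact(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by exact integer combinatorics."""
    num = sum(comb(K, j) * comb(N - K, n - j)
              for j in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))


def hypergeom_tail_enumerated(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by enumerating every size-n draw from an N-element urn."""
    marked = set(range(K))
    hits = sum(1 for draw in combinations(range(N), n)
               if len(marked & set(draw)) >= k)
    return Fraction(hits, comb(N, n))


def bh_reference(p: np.ndarray) -> np.ndarray:
    """Quadratic-time Benjamini-Hochberg step-up.

    q_i = min over all p_j >= p_i of min(1, m * p_j / rank(p_j)), with
    rank(p_j) = number of p-values <= p_j (max rank under ties).
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        candidates = []
        for j in range(m):
            if p[j] >= p[i]:
                rank = int(np.sum(p <= p[j]))
                candidates.append(min(1.0, m * p[j] / rank))
        q[i] = min(candidates)
    return q


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Topological overlap by explicit triple loops."""
    n = a.shape[0]
    k = [sum(a[i][u] for u in range(n)) for i in range(n)]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i][u] * a[u][j] for u in range(n))
            tom[i, j] = (shared + a[i][j]) / (min(k[i], k[j]) + 1 - a[i][j])
    return tom


def average_linkage_naive(d: np.ndarray) -> list[tuple[frozenset[int], frozenset[int], float]]:
    """Naive agglomerative average linkage on a dissimilarity matrix.

    Returns the merge sequence as (cluster_a, cluster_b, height) triples;
    cluster distance is the mean of all cross pairwise dissimilarities.
    """
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(d.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                dist = np.mean([d[i, j] for i in clusters[x] for j in clusters[y]])
                if best is None or dist < best[0]:
                    best = (dist, x, y)
        dist, x, y = best
        a, b = clusters[x], clusters[y]
        merges.append((a, b, dist))
        clusters = [c for idx, c in enumerate(clusters) if idx not in (x, y)]
        clusters.append(a | b)
    return merges


def flood_fill_components(nodes: set[str], edges: list[tuple[str, str]]) -> set[frozenset[str]]:
    """Connected components by breadth-first flood fill."""
    adj: dict[str, set[str]] = {v: set() for v in nodes}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    seen: set[str] = set()
    comps: set[frozenset[str]] = set()
    for start in adj:
        if start in seen:
            continue
        comp, queue = set(), [start]
        while queue:
            v = queue.pop()
            if v in comp:
                continue
            comp.add(v)
            queue.extend(adj[v] - comp)
        seen |= comp
        comps.add(frozenset(comp))
    return comps


def scale_free_regression_reference(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Least-squares log-log regression of the binned connectivity
    distribution, recomputed from first principles."""
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    xs, ys = [], []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (k >= lo) & (k < hi) if b < n_bins - 1 else (k >= lo) & (k <= hi)
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    x, y = np.asarray(xs), np.asarray(ys)
    xbar, ybar = x.mean(), y.mean()
    slope = float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))
    intercept = ybar - slope * xbar
    ss_res = float(np.sum((y - slope * x - intercept) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if slope > 0:
        r2 = -abs(r2)
    return r2, slope
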