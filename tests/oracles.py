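"""Independent brute-force oracles used to verify the graph metrics.

These implementations are deliberately naive (explicit loops, exhaustive
enumeration) and share no code with the package: triangle intensities by
triple loops, all-pairs shortest paths by Floyd–Warshall relaxation, and
modularity by exhaustive search over all set partitions.
"""

from __future__ import annotations

import itertools

import numpy as np


def onnela_clustering_bruteforce(a: np.ndarray) -> float:
    """Node-averaged geometric-mean triangle clustering, by triple loops."""
    n = a.shape[0]
    wmax = a.max()
    if wmax == 0:
        return 0.0
    w = a / wmax
    values = []
    for i in range(n):
        k = int((a[i] > 0).sum())
        if k < 2:
            values.append(0.0)
            continue
        t = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        values.append(t / (k * (k - 1)))
    return float(np.mean(values))


def transitivity_bruteforce(a: np.ndarray) -> float:
    """Total triangle intensity over total connected triples, by loops."""
    n = a.shape[0]
    wmax = a.max()
    if wmax == 0:
        return 0.0
    w = a / wmax
    num = 0.0
    den = 0.0
    for i in range(n):
        k = int((a[i] > 0).sum())
        den += k * (k - 1)
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                num += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
    if den == 0:
        return 0.0
    return float(num / den)


def floyd_warshall_lengths(a: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if a[i, j] > 0:
                d[i, j] = 1.0 / a[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_bruteforce(a: np.ndarray) -> float:
    d = floyd_warshall_lengths(a)
    n = a.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def global_efficiency_bruteforce(a: np.ndarray) -> float:
    d = floyd_warshall_lengths(a)
    n = a.shape[0]
    vals = [
        (1.0 / d[i, j]) if np.isfinite(d[i, j]) and d[i, j] > 0 else 0.0
        for i in range(n)
        for j in range(n)
        if i != j
    ]
    return float(np.mean(vals))


def modularity_of_partition(a: np.ndarray, membership) -> float:
    """Weighted Newman modularity of one partition, by explicit sums."""
    membership = np.asarray(membership)
    two_m = a.sum()
    s = a.sum(axis=1)
    q = 0.0
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += (a[i, j] - s[i] * s[j] / two_m) / two_m
    return float(q)


def set_partitions(n: int):
    """All set partitions of range(n) as membership arrays (restricted growth)."""
    def rec(prefix, maxi):
        if len(prefix) == n:
            yield np.array(prefix)
            return
        for c in range(maxi + 2):
            yield from rec(prefix + [c], max(maxi, c))

    yield from rec([0], 0)


def max_modularity_bruteforce(a: np.ndarray) -> tuple[float, np.ndarray]:
    """Exhaustive-search maximum modularity over all partitions (n <= ~10)."""
    best_q, best_m = -np.inf, None
    for membership in set_partitions(a.shape[0]):
        q = modularity_of_partition(a, membership)
        if q > best_q:
            best_q, best_m = q, membership
    return best_q, best_m


def random_small_network(rng: np.random.Generator, n_max: int = 8):
    """A random small weighted graph with at least one edge (for oracles)."""
    from netnorm import WeightedNetwork

    n = int(rng.integers(3, n_max + 1))
    while True:
        p = rng.uniform(0.25, 0.9)
        a = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    a[i, j] = a[j, i] = rng.uniform(0.05, 1.0)
        if (a > 0).any():
            return WeightedNetwork(a)
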