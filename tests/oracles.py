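"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written directly from first principles (loops,
exhaustive enumeration, closed forms) and deliberately shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def transfer_2x2_bruteforce(coeffs: np.ndarray, fs: float, freq: float) -> np.ndarray:
    """H(f) for a 2-channel MVAR model via the explicit adjugate inverse."""
    p = coeffs.shape[0]
    a = np.eye(2, dtype=complex)
    for n in range(1, p + 1):
        a = a - coeffs[n - 1] * np.exp(-2j * np.pi * freq * n / fs)
    det = a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]
    adj = np.array([[a[1, 1], -a[0, 1]], [-a[1, 0], a[0, 0]]], dtype=complex)
    return adj / det


def transfer_ar1_closed_form(a1: float, fs: float, freq: float) -> complex:
    """Scalar AR(1): H(f) = 1 / (1 - a1 e^{-i 2 pi f / fs})."""
    return 1.0 / (1.0 - a1 * np.exp(-2j * np.pi * freq / fs))


def clustering_bruteforce(adj: np.ndarray) -> float:
    """Directed binary clustering coefficient by exhaustive pair counting.

    ``adj[i, j]`` True means a directed edge j -> i (sink-by-source), the
    package's convention.
    """
    n = adj.shape[0]
    c_sum = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and (adj[i, j] or adj[j, i])]
        e_i = len(nbrs)
        if e_i < 2:
            continue
        count = 0
        for u in nbrs:
            for v in nbrs:
                if u != v and adj[v, u]:  # edge u -> v
                    count += 1
        c_sum += count / (e_i * (e_i - 1))
    return c_sum / n


def density_bruteforce(adj: np.ndarray) -> float:
    n = adj.shape[0]
    edges = sum(
        1 for i in range(n) for j in range(n) if i != j and adj[i, j]
    )
    return edges / (n * (n - 1))


def efficiency_bruteforce(weights: np.ndarray, adj: np.ndarray) -> float:
    """Global efficiency by exhaustive simple-path enumeration (N <= 6).

    Edge u -> v exists iff adj[v, u]; its length is max(w)/w[v, u].
    """
    n = weights.shape[0]
    if not adj.any():
        return 0.0
    w_max = weights[adj].max()

    def edge_len(u: int, v: int) -> float:
        return w_max / weights[v, u] if adj[v, u] else np.inf

    total = 0.0
    for src in range(n):
        for dst in range(n):
            if src == dst:
                continue
            best = np.inf
            middles = [k for k in range(n) if k not in (src, dst)]
            for r in range(len(middles) + 1):
                for mid in itertools.permutations(middles, r):
                    path = (src, *mid, dst)
                    length = sum(edge_len(path[k], path[k + 1]) for k in range(len(path) - 1))
                    best = min(best, length)
            if np.isfinite(best):
                total += 1.0 / best
    return total / (n * (n - 1))


def random_weight_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random DTF-like matrix: entries in [0, 1), zero diagonal."""
    w = rng.uniform(0.0, 1.0, size=(n, n))
    np.fill_diagonal(w, 0.0)
    return w
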