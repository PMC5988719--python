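"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: enumeration with
exact rational arithmetic for the tests, nested loops for morphology.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def ranksum_exact_p_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n, n1) rank subsets."""
    pooled = list(x) + list(y)
    n1 = len(x)
    # mid-ranks
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        r = (i + j + 1) / 2.0  # average of 1-based ranks i+1..j
        for k in range(i, j):
            ranks[order[k]] = r
        i = j
    w_obs = sum(ranks[:n1])
    mu = n1 * sum(ranks) / len(pooled)
    dev = abs(w_obs - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mu) >= dev - 1e-9:
            count += 1
    return count / total


def fisher_exact_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact rational hypergeometric enumeration."""
    r1, c1 = a + b, a + c
    N = a + b + c + d
    if r1 == 0 or r1 == N or c1 == 0 or c1 == N:
        return 1.0
    denom = math.comb(N, r1)
    kmin = max(0, r1 + c1 - N)
    kmax = min(r1, c1)
    probs = {
        k: Fraction(math.comb(c1, k) * math.comb(N - c1, r1 - k), denom)
        for k in range(kmin, kmax + 1)
    }
    p_obs = probs[a]
    cutoff = p_obs + p_obs * Fraction(1, 10**7)
    return float(sum(p for p in probs.values() if p <= cutoff))


def bonferroni_oracle(ps, m=None):
    m = m if m is not None else len(ps)
    return [min(1.0, m * p) for p in ps]


def bh_oracle(ps, m=None):
    """Step-up BH adjusted values, straight from the definition."""
    m = m if m is not None else len(ps)
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    adj = [None] * n
    running_min = 1.0
    for rank_from_top in range(n - 1, -1, -1):
        i = order[rank_from_top]
        val = ps[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        adj[i] = min(1.0, running_min)
    return adj


def grayscale_opening_oracle(img: np.ndarray, footprint: np.ndarray, heights: np.ndarray) -> np.ndarray:
    """Erosion-then-dilation with a non-flat element; out-of-bounds ignored."""
    H, W = img.shape
    r = footprint.shape[0] // 2
    ero = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            best = math.inf
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if not footprint[di + r, dj + r]:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < H and 0 <= jj < W:
                        best = min(best, img[ii, jj] - heights[di + r, dj + r])
            ero[i, j] = best
    dil = np.empty((H, W))
    for i in range(H):
        for j in range(W):
            best = -math.inf
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if not footprint[di + r, dj + r]:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < H and 0 <= jj < W:
                        best = max(best, ero[ii, jj] + heights[di + r, dj + r])
            dil[i, j] = best
    return dil
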