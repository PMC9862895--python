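"""Independent re-implementations used as test oracles.

These deliberately use different algorithmic structure than the package
(recursive enumeration instead of iterative dynamic programming, explicit
loops instead of vectorized views) so that agreement is evidence of
correctness rather than of shared bugs.
"""

from __future__ import annotations

import sys
from functools import lru_cache

import numpy as np


def local_alignment_score_oracle(a: str, b: str, table: dict,
                                 gap_open: float, gap_extend: float) -> float:
    """Best local-alignment score by recursive enumeration of all alignments.

    An alignment is a monotone pairing of a substring of `a` with a
    substring of `b`; a gap run of length L costs gap_open +
    (L-1) * gap_extend.  The recursion enumerates, for every start cell,
    every way to extend or stop, and takes the maximum; the empty alignment
    scores 0.
    """
    sys.setrecursionlimit(10000)

    def sub(x: str, y: str) -> float:
        x = x if (x, x) in table else "X"
        y = y if (y, y) in table else "X"
        return table[(x, y)]

    @lru_cache(maxsize=None)
    def extend(i: int, j: int, state: int) -> float:
        # best score obtainable continuing from (i, j); may stop now (0)
        best = 0.0
        if i < len(a) and j < len(b):
            best = max(best, sub(a[i], b[j]) + extend(i + 1, j + 1, 0))
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            best = max(best, -cost + extend(i + 1, j, 1))
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            best = max(best, -cost + extend(i, j + 1, 2))
        return best

    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            best = max(best, extend(i, j, 0))
    extend.cache_clear()
    return best


def conv3d_oracle(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3D "same" convolution (stride 1, zero padding) with explicit loops."""
    n, c_in, d, h, wd = x.shape
    c_out, _, k, _, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    out = np.zeros((n, c_out, d, h, wd))
    for bi in range(n):
        for o in range(c_out):
            for z in range(d):
                for y in range(h):
                    for xx in range(wd):
                        patch = xp[bi, :, z:z + k, y:y + k, xx:xx + k]
                        out[bi, o, z, y, xx] = np.sum(patch * w[o]) + b[o]
    return out


def maxpool_oracle(x: np.ndarray) -> np.ndarray:
    """2x2x2 stride-2 max pooling with explicit loops."""
    n, c, d, h, w = x.shape
    d2, h2, w2 = d // 2, h // 2, w // 2
    out = np.zeros((n, c, d2, h2, w2), dtype=x.dtype)
    for z in range(d2):
        for y in range(h2):
            for xx in range(w2):
                out[:, :, z, y, xx] = x[:, :, 2 * z:2 * z + 2,
                                        2 * y:2 * y + 2,
                                        2 * xx:2 * xx + 2].max(axis=(2, 3, 4))
    return out


def components_oracle(points: np.ndarray, cutoff: float) -> list:
    """Connected components of the strict distance graph via union-find."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) < cutoff:
                parent[find(i)] = find(j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted([sorted(g) for g in groups.values()])


def percentile_oracle(values, q: float) -> float:
    """Percentile with linear interpolation, computed from first principles."""
    xs = sorted(float(v) for v in values)
    if len(xs) == 1:
        return xs[0]
    pos = q / 100.0 * (len(xs) - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(xs) - 1)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac
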