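"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (breadth-first search, per-pixel loops,
textbook formulas) kept separate from the package so the tests compare two
independent routes to the same answer.
"""
from __future__ import annotations

from collections import deque

import numpy as np


def bfs_grow(gray: np.ndarray, seed: tuple[int, int], tolerance: int,
             constraint: np.ndarray | None = None, connectivity: int = 4) -> np.ndarray:
    """Brute-force breadth-first region growing from the seed pixel."""
    h, w = gray.shape
    sr, sc = seed
    seed_val = int(gray[sr, sc])
    ok = np.abs(gray.astype(int) - seed_val) <= tolerance
    if constraint is not None:
        ok &= constraint.astype(bool)
    out = np.zeros((h, w), dtype=bool)
    if not ok[sr, sc]:
        return out
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    queue = deque([(sr, sc)])
    out[sr, sc] = True
    while queue:
        r, c = queue.popleft()
        for dr, dc in steps:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and ok[rr, cc] and not out[rr, cc]:
                out[rr, cc] = True
                queue.append((rr, cc))
    return out


def direct_moments(gray: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    """Pixel-by-pixel (n, Σgray, Σgray²) accumulation."""
    n = s = ss = 0
    h, w = gray.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                v = int(gray[r, c])
                n += 1
                s += v
                ss += v * v
    return n, s, ss


def pearson_chi2(table: np.ndarray) -> float:
    """Textbook Σ(O−E)²/E on a contingency table."""
    obs = np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row * col / obs.sum()
    return float(((obs - exp) ** 2 / exp).sum())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap coefficient of two masks."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
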