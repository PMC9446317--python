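"""Brute-force reference implementations for validation.

These are deliberately naive: an iterative flood fill for component counting,
an exhaustive rotation-grid search for the oriented bounding box, and exact
enumeration of the conditional (fixed-margin) permutation distribution of the
2x2 chi-squared statistic. They share no code with the production paths in
:mod:`lesionmorph.shape` / :mod:`lesionmorph.stats` and exist so tests and the
reproduction script can check the fast implementations against first
principles on small instances.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "flood_fill_count",
    "axis_rotation_obb_volume",
    "exact_chi2_perm_p_2x2",
]


def _neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if (connectivity == 6 and order == 1) or \
           (connectivity == 18 and order <= 2) or \
           (connectivity == 26):
            offs.append(d)
    return offs


def flood_fill_count(mask: np.ndarray, connectivity: int = 26) -> int:
    """Count connected components by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    offsets = _neighbor_offsets(connectivity)
    visited = np.zeros_like(mask)
    shape = mask.shape
    count = 0
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                ni, nj, nk = i + di, j + dj, k + dk
                if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2] \
                        and mask[ni, nj, nk] and not visited[ni, nj, nk]:
                    visited[ni, nj, nk] = True
                    stack.append((ni, nj, nk))
    return count


def _axis_rotation_matrix(axis: int, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    rot = np.eye(3)
    a, b = [i for i in range(3) if i != axis]
    rot[a, a] = c
    rot[a, b] = -s
    rot[b, a] = s
    rot[b, b] = c
    return rot


def axis_rotation_obb_volume(
    points: np.ndarray,
    axis: int,
    step_deg: float = 1.0,
) -> float:
    """Minimum bounding-box volume over all rotations about one coordinate
    axis, searched exhaustively on a ``step_deg`` grid over [0, 90)."""
    points = np.asarray(points, dtype=float)
    best = np.inf
    for deg in np.arange(0.0, 90.0, step_deg):
        rot = _axis_rotation_matrix(axis, np.deg2rad(deg))
        proj = points @ rot
        vol = float(np.prod(proj.max(axis=0) - proj.min(axis=0)))
        best = min(best, vol)
    return best


def chi2_statistic(table: np.ndarray) -> float:
    """Pearson chi-squared statistic without continuity correction."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def exact_chi2_perm_p_2x2(table: np.ndarray) -> float:
    """Exact conditional p-value P(chi² >= observed | margins) for a 2x2 table,
    by enumerating the hypergeometric distribution of the top-left cell."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2):
        raise ValueError("exact enumeration implemented for 2x2 tables only")
    n = table.sum()
    r1 = table[0].sum()
    c1 = table[:, 0].sum()
    observed = chi2_statistic(table)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    p = 0.0
    for a in range(lo, hi + 1):
        t = np.array([[a, r1 - a], [c1 - a, n - r1 - c1 + a]])
        if chi2_statistic(t) >= observed - 1e-12:
            p += hypergeom.pmf(a, n, c1, r1)
    return float(min(p, 1.0))
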