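"""Brute-force reference implementations of the gray-level matrices.

These deliberately use naive per-pixel loops and flood fill — algorithms
independent of the vectorized builders they are checked against.
"""

from __future__ import annotations

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_bruteforce(
    q: np.ndarray, n_gray_levels: int, distance: int = 1, angle: int = 0
) -> np.ndarray:
    """Count every ordered pixel pair at the offset, in both directions."""
    dr, dc = OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    h, w = q.shape
    mat = np.zeros((n_gray_levels, n_gray_levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                mat[q[r, c] - 1, q[r2, c2] - 1] += 1
                mat[q[r2, c2] - 1, q[r, c] - 1] += 1
    return mat


def glrlm_bruteforce(q: np.ndarray, n_gray_levels: int, angle: int = 0) -> np.ndarray:
    """Enumerate maximal runs by walking each one from its starting pixel."""
    dr, dc = OFFSETS[angle]
    h, w = q.shape
    mat = np.zeros((n_gray_levels, max(h, w)), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            prev_same = 0 <= pr < h and 0 <= pc < w and q[pr, pc] == q[r, c]
            if prev_same:
                continue  # not the start of a maximal run
            length = 0
            rr, cc = r, c
            while 0 <= rr < h and 0 <= cc < w and q[rr, cc] == q[r, c]:
                length += 1
                rr, cc = rr + dr, cc + dc
            mat[q[r, c] - 1, length - 1] += 1
    return mat


def glszm_bruteforce(q: np.ndarray, n_gray_levels: int) -> dict[tuple[int, int], int]:
    """Flood-fill 8-connected zones; returns {(level, size): count}."""
    h, w = q.shape
    seen = np.zeros((h, w), dtype=bool)
    zones: dict[tuple[int, int], int] = {}
    for r in range(h):
        for c in range(w):
            if seen[r, c]:
                continue
            level = q[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                y, x = stack.pop()
                size += 1
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        ny, nx = y + dy, x + dx
                        if (
                            0 <= ny < h and 0 <= nx < w
                            and not seen[ny, nx] and q[ny, nx] == level
                        ):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
            key = (int(level), size)
            zones[key] = zones.get(key, 0) + 1
    return zones


def matrix_to_zone_dict(mat: np.ndarray) -> dict[tuple[int, int], int]:
    out = {}
    for i, j in zip(*np.nonzero(mat)):
        out[(int(i) + 1, int(j) + 1)] = int(mat[i, j])
    return out


def auc_pairwise(scores, is_positive) -> float:
    """Mann-Whitney AUC: P(random positive > random negative), ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    is_positive = np.asarray(is_positive, dtype=bool)
    pos = scores[is_positive]
    neg = scores[~is_positive]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
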