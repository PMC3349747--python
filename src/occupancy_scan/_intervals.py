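"""Small interval-arithmetic helpers shared across modules.

All intervals are 0-based half-open ``(start, end)`` tuples on a single
chromosome; callers keep per-chromosome collections.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping or touching half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval ({s}, {e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_arrays(merged: Sequence[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    """Starts/ends arrays for a merged, sorted interval list."""
    if not merged:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def points_in_intervals(starts: np.ndarray, ends: np.ndarray, pos) -> np.ndarray:
    """Boolean membership of position(s) in a merged interval set."""
    pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    hit = np.zeros(pos.shape, dtype=bool)
    hit[ok] = pos[ok] < ends[idx[ok]]
    return hit


def intersect_merged(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection segments of two merged interval lists (two-pointer sweep)."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out
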