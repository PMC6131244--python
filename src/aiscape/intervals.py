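"""Half-open interval arithmetic on numpy arrays.

Intervals are ``(starts, ends)`` pairs of equal-length integer arrays with
``starts < ends``. Used for AI-segment unions, callable-mask intersection
and coverage counting; small enough that a dedicated interval library is
not warranted.
"""

from __future__ import annotations

import numpy as np


def union(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/touching intervals into a disjoint sorted set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def total_length(starts, ends) -> int:
    s, e = union(starts, ends)
    return int((e - s).sum())


def intersect(a_starts, a_ends, b_starts, b_ends) -> tuple[np.ndarray, np.ndarray]:
    """Intersection of two interval sets (each may be unsorted/overlapping)."""
    a_s, a_e = union(a_starts, a_ends)
    b_s, b_e = union(b_starts, b_ends)
    out_s, out_e = [], []
    i = j = 0
    while i < len(a_s) and j < len(b_s):
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if lo < hi:
            out_s.append(lo)
            out_e.append(hi)
        if a_e[i] <= b_e[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def overlap_length(a_starts, a_ends, b_starts, b_ends) -> int:
    s, e = intersect(a_starts, a_ends, b_starts, b_ends)
    return int((e - s).sum())


def clip(starts, ends, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
    """Clip intervals to ``[lo, hi)``, dropping those that become empty."""
    s = np.clip(np.asarray(starts, dtype=np.int64), lo, hi)
    e = np.clip(np.asarray(ends, dtype=np.int64), lo, hi)
    keep = s < e
    return s[keep], e[keep]


def points_in(points, starts, ends) -> np.ndarray:
    """Boolean mask: which points fall inside the (disjoint, sorted) intervals."""
    s, e = union(starts, ends)
    pts = np.asarray(points, dtype=np.int64)
    if s.size == 0:
        return np.zeros(pts.shape, dtype=bool)
    idx = np.searchsorted(s, pts, side="right") - 1
    ok = idx >= 0
    ok[ok] &= pts[ok] < e[idx[ok]]
    return ok
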