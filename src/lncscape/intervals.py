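"""Small genomic-interval utilities on 0-based half-open coordinates.

Intervals are (start, end) integer pairs with start < end. All functions
return sorted, pairwise-disjoint interval lists.
"""

from __future__ import annotations

import numpy as np

Interval = tuple[int, int]


def merge(intervals: list[Interval]) -> list[Interval]:
    """Merge overlapping or touching intervals into a disjoint sorted set."""
    if not intervals:
        return []
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def total_length(intervals: list[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def subtract(a: list[Interval], b: list[Interval]) -> list[Interval]:
    """Bases of ``a`` not covered by ``b``. Both inputs may be unmerged."""
    a = merge(a)
    b = merge(b)
    out: list[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def intersect_length(a: list[Interval], b: list[Interval]) -> int:
    """Total overlap in bases between two interval sets."""
    a = merge(a)
    b = merge(b)
    i = j = 0
    tot = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            tot += e - s
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return tot


def overlaps_point_window(intervals: np.ndarray, lo: int, hi: int) -> bool:
    """True if any interval in an (n, 2) array intersects [lo, hi)."""
    if len(intervals) == 0:
        return False
    return bool(np.any((intervals[:, 0] < hi) & (intervals[:, 1] > lo)))
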