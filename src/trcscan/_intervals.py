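"""Tiny interval-set arithmetic on lists of 0-based half-open (start, end) tuples.

These operate on per-gene interval lists (a handful of exons), where building
genome-scale interval containers would be overkill. All functions return
merged, sorted, non-empty intervals.
"""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or book-ended intervals; drop empty ones."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Interval-set intersection a ∩ b."""
    a, b = merge(a), merge(b)
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Interval-set difference a \\ b."""
    a, b = merge(a), merge(b)
    out: List[Interval] = []
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
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def clip(intervals: Iterable[Interval], lo: int, hi: int) -> List[Interval]:
    """Clip every interval to [lo, hi); drop the ones that fall empty."""
    return [(max(s, lo), min(e, hi)) for s, e in intervals if min(e, hi) > max(s, lo)]
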