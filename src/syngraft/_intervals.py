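"""Exact integer interval arithmetic (0-based half-open) used by the
TE accounting and annotation summaries.

A sweep-line over interval endpoints gives exact base counts without
materialising per-base masks, so the same code scales from unit-test
fixtures to chromosome-sized annotations.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def union_bp(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def intersect_bp(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> int:
    """Bases covered by both interval sets (each set unioned first)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    i = j = total = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if e > s:
            total += e - s
        if ma[i][1] < mb[j][1]:
            i += 1
        else:
            j += 1
    return total


def coverage_at_least(sources: Sequence[Sequence[tuple[int, int]]], depth: int) -> int:
    """Bases covered by >= `depth` distinct sources.

    Each source is unioned first so duplicated intervals within a single
    source never inflate the depth.
    """
    events: list[tuple[int, int]] = []
    for src in sources:
        for s, e in merge_intervals(src):
            events.append((s, 1))
            events.append((e, -1))
    events.sort()
    total = 0
    cur = 0
    prev = None
    for pos, delta in events:
        if prev is not None and cur >= depth:
            total += pos - prev
        cur += delta
        prev = pos
    return total


def clip_interval(start: int, end: int, length: int) -> tuple[int, int]:
    return max(0, start), min(length, end)
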