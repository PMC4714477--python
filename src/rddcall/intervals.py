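"""Merged genomic interval sets with point/overlap queries.

All coordinates are 0-based half-open. Intervals are merged per chromosome
at construction, so membership queries reduce to a single bisect.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Dict, Iterable, Iterator, List, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Merge overlapping or book-ended intervals into a sorted disjoint list."""
    merged: List[Interval] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            if end > merged[-1][1]:
                merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))
    return merged


def subtract_intervals(a: Iterable[Interval], b: Iterable[Interval]) -> List[Interval]:
    """Set difference a \\ b over disjoint sorted interval lists."""
    result: List[Interval] = []
    b = list(b)
    for start, end in a:
        cur = start
        for bs, be in b:
            if be <= cur or bs >= end:
                continue
            if bs > cur:
                result.append((cur, bs))
            cur = max(cur, be)
            if cur >= end:
                break
        if cur < end:
            result.append((cur, end))
    return result


class IntervalSet:
    """A per-chromosome set of merged intervals supporting point queries."""

    def __init__(self, by_chrom: Dict[str, Iterable[Interval]] | None = None):
        self._starts: Dict[str, List[int]] = {}
        self._ends: Dict[str, List[int]] = {}
        if by_chrom:
            for chrom, ivs in by_chrom.items():
                merged = merge_intervals(ivs)
                self._starts[chrom] = [s for s, _ in merged]
                self._ends[chrom] = [e for _, e in merged]

    @classmethod
    def from_tuples(cls, tuples: Iterable[Tuple[str, int, int]]) -> "IntervalSet":
        by_chrom: Dict[str, List[Interval]] = {}
        for chrom, start, end in tuples:
            by_chrom.setdefault(chrom, []).append((start, end))
        return cls(by_chrom)

    def contains(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, pos) - 1
        return i >= 0 and pos < self._ends[chrom][i]

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect_right(starts, end - 1) - 1
        return i >= 0 and start < self._ends[chrom][i]

    def intervals(self, chrom: str | None = None) -> Iterator[Tuple[str, int, int]]:
        chroms = [chrom] if chrom is not None else sorted(self._starts)
        for c in chroms:
            for s, e in zip(self._starts.get(c, []), self._ends.get(c, [])):
                yield (c, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def __bool__(self) -> bool:  # empty set is falsy but still queryable
        return len(self) > 0
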