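"""Half-open interval algebra on per-contig sorted, disjoint intervals.

All coordinates are 0-based half-open (BED convention).  ``IntervalSet``
is the canonical form: per contig a pair of arrays ``(starts, ends)``
that are sorted, non-overlapping and non-abutting (merged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class IntervalSet:
    """Contig-keyed sorted disjoint half-open intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, s, e in records:
            by_contig.setdefault(contig, []).append((int(s), int(e)))
        return cls({c: merge_intervals(ivs) for c, ivs in by_contig.items()})

    def to_records(self) -> list[tuple[str, int, int]]:
        return [
            (c, s, e) for c in sorted(self.intervals) for s, e in self.intervals[c]
        ]

    def total_length(self) -> int:
        return sum(e - s for ivs in self.intervals.values() for s, e in ivs)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet.from_records(self.to_records() + other.to_records())

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases in ``self`` not covered by ``other``."""
        out: dict[str, list[tuple[int, int]]] = {}
        for contig, ivs in self.intervals.items():
            cut = other.intervals.get(contig, [])
            kept: list[tuple[int, int]] = []
            for s, e in ivs:
                cur = s
                for cs, ce in cut:
                    if ce <= cur or cs >= e:
                        continue
                    if cs > cur:
                        kept.append((cur, cs))
                    cur = max(cur, ce)
                    if cur >= e:
                        break
                if cur < e:
                    kept.append((cur, e))
            if kept:
                out[contig] = kept
        return IntervalSet(out)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        return self.subtract(self.subtract(other))

    def covered_length(self, contig: str, start: int, end: int) -> int:
        """Bases of ``[start, end)`` on ``contig`` covered by this set."""
        n = 0
        for s, e in self.intervals.get(contig, []):
            n += max(0, min(e, end) - max(s, start))
        return n

    def contains_region(self, contig: str, start: int, end: int) -> bool:
        return self.covered_length(contig, start, end) == end - start


def coverage_intervals(
    intervals: Iterable[tuple[int, int]], min_count: int
) -> list[tuple[int, int]]:
    """Bases covered by at least ``min_count`` of the given intervals.

    Sweep-line over start/end events; intervals may overlap arbitrarily.
    """
    events: list[tuple[int, int]] = []
    for s, e in intervals:
        events.append((int(s), 1))
        events.append((int(e), -1))
    events.sort()
    out: list[tuple[int, int]] = []
    depth = 0
    open_start: int | None = None
    i = 0
    while i < len(events):
        pos = events[i][0]
        while i < len(events) and events[i][0] == pos:
            depth += events[i][1]
            i += 1
        if depth >= min_count and open_start is None:
            open_start = pos
        elif depth < min_count and open_start is not None:
            if pos > open_start:
                out.append((open_start, pos))
            open_start = None
    return merge_intervals(out) if out else []


def coverage_mask(
    intervals: Iterable[tuple[int, int]], length: int
) -> np.ndarray:
    """Per-base coverage count over ``[0, length)`` — brute-force helper."""
    cov = np.zeros(length, dtype=int)
    for s, e in intervals:
        cov[max(0, s) : min(length, e)] += 1
    return cov
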