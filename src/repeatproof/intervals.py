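"""Half-open interval arithmetic shared by the coverage and gap modules.

All coordinates in this package are 0-based half-open; conversions to and
from 1-based inclusive (GFF3, show-coords) happen only in :mod:`align_io`.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals as a sorted list of disjoint intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def complement(
    intervals: Iterable[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    """Maximal uncovered intervals on [0, length), terminal gaps included."""
    gaps = []
    pos = 0
    for s, e in merge_intervals(intervals):
        if s > pos:
            gaps.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        gaps.append((pos, length))
    return gaps


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def intersects_any(iv: tuple[int, int], others: Sequence[tuple[int, int]]) -> bool:
    """True if ``iv`` overlaps >=1 bp of any interval (others need not be sorted)."""
    return any(overlap_length(iv, o) > 0 for o in others)
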