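"""Half-open genomic interval arithmetic.

All intervals in this package are 0-based, half-open ``(start, end)`` pairs;
conversions from 1-based formats (GFF3, CGmap positions) happen only at parse
and write boundaries.  These primitives back the per-gene feature lengths and
the TE-overlap accounting, where overlapping repeat annotations must be merged
before summing so that no base pair is counted twice.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or book-ended half-open intervals.

    Book-ended intervals (``[a,b)`` and ``[b,c)``) are merged into one, which
    is what matters for length accounting.  Zero-length intervals vanish.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    if not ivs:
        return []
    merged = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = merged[-1]
        if s <= le:
            if e > le:
                merged[-1] = (ls, e)
        else:
            merged.append((s, e))
    return merged


def total_length(intervals: Iterable[Interval]) -> int:
    """Total base pairs covered after merging."""
    return sum(e - s for s, e in merge_intervals(intervals))


def intersect_and_merge(
    a: Sequence[Interval], b: Sequence[Interval]
) -> tuple[int, list[Interval]]:
    """Overlap of two interval sets, merged so no base is counted twice.

    Returns ``(overlap_length, merged_overlap_segments)``.  Both inputs are
    merged first, so overlapping annotations on either side (for example two
    nested repeat records) contribute only once — mirroring an
    intersect-then-merge on BED tracks.
    """
    ma, mb = merge_intervals(a), merge_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(ma) and j < len(mb):
        s = max(ma[i][0], mb[j][0])
        e = min(ma[i][1], mb[j][1])
        if e > s:
            out.append((s, e))
        if ma[i][1] <= mb[j][1]:
            i += 1
        else:
            j += 1
    return sum(e - s for s, e in out), out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Parts of ``a`` not covered by ``b`` (both merged first)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    out: list[Interval] = []
    j = 0
    for s, e in ma:
        cur = s
        while j < len(mb) and mb[j][1] <= cur:
            j += 1
        k = j
        while k < len(mb) and mb[k][0] < e:
            bs, be = mb[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def gaps_between(intervals: Sequence[Interval]) -> list[Interval]:
    """Gaps between consecutive merged intervals (e.g. introns between exons)."""
    merged = merge_intervals(intervals)
    return [
        (merged[i][1], merged[i + 1][0])
        for i in range(len(merged) - 1)
        if merged[i + 1][0] > merged[i][1]
    ]
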