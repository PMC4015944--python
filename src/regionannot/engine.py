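"""Per-chromosome annotation index with sweep-cursor overlap and neighbor queries.

The index keeps, for every chromosome, the annotations of one source
sorted by (start, end, name).  Overlap queries are answered with a
sweep: queries are sorted internally by (chromosome, start), and a
memoized cursor per chromosome skips annotations whose end precedes the
current query start — such annotations can never overlap the current or
any later query in the sorted batch.  The cursor advances past the front
of the list only; annotations between the cursor and the start-bound
break are scanned but not reported, which keeps the sweep exactly
equivalent to the all-pairs definition even in the presence of long
annotations that span many queries.  Results are returned in the
caller's original query order.

Neighbors — the closest *non-overlapping* annotation on each side — are
answered by binary search on two sorted views: left neighbors need the
annotation with maximal end at or before the query start, right
neighbors the one with minimal start at or after the query end.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from .regions import GenomicRegion
from .taxonomy import overlaps

__all__ = [
    "AnnotationIndex",
    "NeighborHit",
    "NeighborResult",
    "build_index",
    "find_overlaps",
    "find_neighbors",
]


@dataclass(frozen=True, slots=True)
class NeighborHit:
    """One neighboring annotation and its gap to the query.

    For a left neighbor the distance is measured from the query start to
    the annotation end; for a right neighbor from the query end to the
    annotation start.  Both are non-negative; an abutting annotation is
    a neighbor at distance 0.
    """

    region: GenomicRegion
    distance: int


@dataclass(frozen=True, slots=True)
class NeighborResult:
    left: NeighborHit | None
    right: NeighborHit | None


class AnnotationIndex:
    """Start-sorted annotations of one source, partitioned by chromosome."""

    def __init__(self, source_name: str, per_chrom: dict[str, list[GenomicRegion]]):
        self.source_name = source_name
        self.per_chrom = per_chrom
        # parallel start arrays for binary search / sweep bounds
        self._starts = {c: [r.start for r in lst] for c, lst in per_chrom.items()}
        # view sorted by (end, start, name) for left-neighbor search
        self._by_end = {
            c: sorted(lst, key=lambda r: (r.end, r.start, r.name or ""))
            for c, lst in per_chrom.items()
        }
        self._ends = {c: [r.end for r in lst] for c, lst in self._by_end.items()}
        self.cursor: dict[str, int] = {c: 0 for c in per_chrom}

    def __len__(self) -> int:
        return sum(len(lst) for lst in self.per_chrom.values())

    def reset_cursors(self) -> None:
        for c in self.cursor:
            self.cursor[c] = 0


def build_index(
    annotations: Iterable[GenomicRegion], source_name: str = "annotations"
) -> AnnotationIndex:
    """Partition annotations by chromosome and sort each list by (start, end, name).

    Duplicates are retained; an empty input yields a valid empty index.
    """
    per_chrom: dict[str, list[GenomicRegion]] = {}
    for r in annotations:
        per_chrom.setdefault(r.chrom, []).append(r)
    for lst in per_chrom.values():
        lst.sort(key=lambda r: (r.start, r.end, r.name or ""))
    return AnnotationIndex(source_name, per_chrom)


def find_overlaps(
    index: AnnotationIndex, queries: Sequence[GenomicRegion]
) -> list[list[GenomicRegion]]:
    """All index annotations overlapping each query, in (start, end, name) order.

    Queries need not be pre-sorted; the engine sorts internally and
    restores input order, so result ``i`` always belongs to query ``i``.
    """
    results: list[list[GenomicRegion]] = [[] for _ in queries]
    order = sorted(range(len(queries)), key=lambda i: queries[i].sort_key())
    index.reset_cursors()
    per_chrom, cursor = index.per_chrom, index.cursor
    for i in order:
        q = queries[i]
        lst = per_chrom.get(q.chrom)
        if not lst:
            continue
        cur = cursor[q.chrom]
        n = len(lst)
        # annotations ending strictly before the query start can never
        # overlap this or any later query of the sorted batch
        while cur < n and lst[cur].end < q.start:
            cur += 1
        cursor[q.chrom] = cur
        hits = results[i]
        j = cur
        qe = q.end
        while j < n:
            a = lst[j]
            if a.start > qe:
                break
            if overlaps(q, a):
                hits.append(a)
            j += 1
    return results


def _left_neighbor(index: AnnotationIndex, q: GenomicRegion) -> NeighborHit | None:
    lst = index._by_end.get(q.chrom)
    if not lst:
        return None
    ends = index._ends[q.chrom]
    k = bisect_right(ends, q.start) - 1
    # skip annotations that touch the query under the zero-length
    # boundary rules (they overlap, hence are not neighbors)
    while k >= 0 and overlaps(q, lst[k]):
        k -= 1
    if k < 0:
        return None
    best = lst[k]
    # ties on (end, start): lexicographically smallest name wins
    j = k - 1
    while j >= 0 and lst[j].end == best.end and lst[j].start == best.start:
        if (lst[j].name or "") < (best.name or ""):
            best = lst[j]
        j -= 1
    return NeighborHit(best, q.start - best.end)


def _right_neighbor(index: AnnotationIndex, q: GenomicRegion) -> NeighborHit | None:
    lst = index.per_chrom.get(q.chrom)
    if not lst:
        return None
    starts = index._starts[q.chrom]
    k = bisect_left(starts, q.end)
    while k < len(lst) and overlaps(q, lst[k]):
        k += 1
    if k >= len(lst):
        return None
    return NeighborHit(lst[k], lst[k].start - q.end)


def find_neighbors(
    index: AnnotationIndex, queries: Sequence[GenomicRegion]
) -> list[NeighborResult]:
    """Closest non-overlapping annotation on each side of every query.

    Left = maximal end at or before the query start (ties: maximal
    start, then smallest name); right = minimal start at or after the
    query end (ties: minimal end, then smallest name).  An annotation
    overlapping the query is never a neighbor; a side with no candidate
    is ``None``.
    """
    return [
        NeighborResult(_left_neighbor(index, q), _right_neighbor(index, q))
        for q in queries
    ]
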