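"""Overlap predicate and the 16-class overlap configuration taxonomy.

Between a query region and an annotation region on the same chromosome
there are exactly 16 realizable overlap configurations once zero-length
elements are admitted: the 9 Allen-style relations with a non-empty
intersection between two proper intervals, 3 configurations of a
zero-length query against a proper annotation, 3 of a zero-length
annotation against a proper query, and 1 of two coincident zero-length
elements.

The overlap convention that realizes exactly these 16 classes is:

* two proper intervals overlap iff their half-open intersection is
  non-empty (``q.start < a.end and a.start < q.end``); abutting
  intervals do **not** overlap;
* a zero-length element at ``p`` overlaps a proper interval ``[s, e)``
  iff ``s <= p <= e`` — an insertion point sitting on either boundary
  touches the interval;
* two zero-length elements overlap iff they coincide.

Each overlapping pair is classified by the four cross-comparisons
``(qs vs as, qs vs ae, qe vs as, qe vs ae)`` together with the two
zero-length flags.  Class ids are assigned in a canonical repo order:
proper/proper classes 1-9, zero-length-query classes 10-12,
zero-length-annotation classes 13-15, both-zero-length class 16; within
each group patterns are sorted with LESS < EQUAL < GREATER.
``CLASS_TABLE`` is the machine-readable form of this table.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

from .regions import GenomicRegion, PositionRelation, compare_positions

__all__ = [
    "OverlapClass",
    "CLASS_TABLE",
    "overlaps",
    "classify_overlap",
    "enumerate_overlap_classes",
    "OverlapContractError",
]

_L = PositionRelation.LESS
_E = PositionRelation.EQUAL
_G = PositionRelation.GREATER


class OverlapContractError(ValueError):
    """classify_overlap was called on a non-overlapping pair."""


@dataclass(frozen=True, slots=True)
class OverlapClass:
    """One realizable overlap configuration.

    ``pattern`` holds the relations (query start vs annotation start,
    query start vs annotation end, query end vs annotation start,
    query end vs annotation end); ``q_is_point`` / ``a_is_point`` flag
    zero-length participants.  ``diagram`` is a two-line ASCII sketch
    (``#`` query, ``=`` annotation, ``|`` zero-length element).
    """

    class_id: int
    name: str
    pattern: tuple[PositionRelation, PositionRelation, PositionRelation, PositionRelation]
    q_is_point: bool
    a_is_point: bool
    diagram: str


def _cls(cid, name, pattern, qp, ap, diagram):
    return OverlapClass(cid, name, pattern, qp, ap, diagram)


CLASS_TABLE: tuple[OverlapClass, ...] = (
    # proper query vs proper annotation (9 Allen relations with non-empty
    # half-open intersection)
    _cls(1, "left-overlap", (_L, _L, _G, _L), False, False,
         "query  ####\nannot    ===="),
    _cls(2, "finished-by", (_L, _L, _G, _E), False, False,
         "query  ######\nannot    ===="),
    _cls(3, "contains", (_L, _L, _G, _G), False, False,
         "query  ########\nannot    ===="),
    _cls(4, "starts", (_E, _L, _G, _L), False, False,
         "query  ####\nannot  ========"),
    _cls(5, "equals", (_E, _L, _G, _E), False, False,
         "query  ####\nannot  ===="),
    _cls(6, "started-by", (_E, _L, _G, _G), False, False,
         "query  ########\nannot  ===="),
    _cls(7, "during", (_G, _L, _G, _L), False, False,
         "query    ####\nannot  ========"),
    _cls(8, "finishes", (_G, _L, _G, _E), False, False,
         "query    ####\nannot  ======"),
    _cls(9, "right-overlap", (_G, _L, _G, _G), False, False,
         "query    ####\nannot  ===="),
    # zero-length query vs proper annotation
    _cls(10, "point-query-at-annotation-start", (_E, _L, _E, _L), True, False,
         "query  |\nannot  ===="),
    _cls(11, "point-query-inside", (_G, _L, _G, _L), True, False,
         "query   |\nannot  ===="),
    _cls(12, "point-query-at-annotation-end", (_G, _E, _G, _E), True, False,
         "query      |\nannot  ===="),
    # proper query vs zero-length annotation
    _cls(13, "point-annotation-at-query-end", (_L, _L, _E, _E), False, True,
         "query  ####\nannot      |"),
    _cls(14, "point-annotation-inside", (_L, _L, _G, _G), False, True,
         "query  ####\nannot   |"),
    _cls(15, "point-annotation-at-query-start", (_E, _E, _G, _G), False, True,
         "query  ####\nannot  |"),
    # both zero-length
    _cls(16, "coincident-points", (_E, _E, _E, _E), True, True,
         "query  |\nannot  |"),
)

_BY_KEY: dict[tuple, OverlapClass] = {
    (c.pattern, c.q_is_point, c.a_is_point): c for c in CLASS_TABLE
}
assert len(_BY_KEY) == 16


def overlaps(q: GenomicRegion, a: GenomicRegion) -> bool:
    """True iff the two regions share at least one position.

    Half-open intersection for proper intervals; boundary-inclusive
    containment for zero-length elements; coincidence for two
    zero-length elements.  Regions on different chromosomes never
    overlap.
    """
    if q.chrom != a.chrom:
        return False
    q_point = q.start == q.end
    a_point = a.start == a.end
    if not q_point and not a_point:
        return q.start < a.end and a.start < q.end
    if q_point and not a_point:
        return a.start <= q.start <= a.end
    if a_point and not q_point:
        return q.start <= a.start <= q.end
    return q.start == a.start


def classify_overlap(q: GenomicRegion, a: GenomicRegion) -> OverlapClass:
    """Classify an overlapping pair into one of the 16 configurations.

    Raises :class:`OverlapContractError` when the pair does not overlap.
    """
    if not overlaps(q, a):
        raise OverlapContractError(
            f"classify_overlap called on non-overlapping pair "
            f"{q.chrom}:{q.start}-{q.end} vs {a.chrom}:{a.start}-{a.end}"
        )
    pattern = (
        compare_positions(q.start, a.start),
        compare_positions(q.start, a.end),
        compare_positions(q.end, a.start),
        compare_positions(q.end, a.end),
    )
    return _BY_KEY[(pattern, q.is_zero_length, a.is_zero_length)]


def enumerate_overlap_classes(
    grid_size: int = 5, proper_only: bool = False
) -> frozenset[OverlapClass]:
    """Brute-force the distinct overlap classes on a small coordinate grid.

    Enumerates every quadruple ``(qs <= qe, as <= ae)`` over offsets
    ``0 .. grid_size - 1``, keeps the overlapping pairs, and collects
    their classifications.  For any ``grid_size >= 5`` the result is the
    full set of 16 classes (9 when restricted to proper intervals).
    """
    if grid_size < 5:
        raise ValueError("grid_size must be at least 5 to realize every class")
    found: set[OverlapClass] = set()
    pairs = list(combinations_with_replacement(range(grid_size), 2))
    for qs, qe in pairs:
        if proper_only and qs == qe:
            continue
        q = GenomicRegion("chr1", qs, qe)
        for as_, ae in pairs:
            if proper_only and as_ == ae:
                continue
            a = GenomicRegion("chr1", as_, ae)
            if overlaps(q, a):
                found.add(classify_overlap(q, a))
    return frozenset(found)
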