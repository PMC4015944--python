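"""Strand-aware anchored distances between queries and neighboring annotations.

A distance is measured between two *anchors*: one position of the
annotation (its 5' end, 3' end, start, end, or center) and one position
of the query (start, end, or center).  The 5' end of an annotation is
its start base on the plus strand and its end base on the minus strand,
and vice versa for the 3' end, so the 5'/3' anchors require strand
information.

Distances are signed on the reference strand: positive when the
annotation anchor lies at a larger reference coordinate than the query
anchor (the usual convention for TSS-distance reports).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .engine import AnnotationIndex, find_neighbors
from .regions import GenomicRegion, RegionError, StrandRequiredError

__all__ = [
    "ANNOTATION_ANCHORS",
    "QUERY_ANCHORS",
    "AnchorSpec",
    "AnchoredDistance",
    "resolve_anchor",
    "anchored_distance",
    "distance_annotate",
]

ANNOTATION_ANCHORS = ("five_prime", "three_prime", "start", "end", "center")
QUERY_ANCHORS = ("start", "end", "center")


@dataclass(frozen=True, slots=True)
class AnchorSpec:
    """Which annotation position and which query position to measure between."""

    annotation_anchor: str = "five_prime"
    query_anchor: str = "start"

    def __post_init__(self) -> None:
        if self.annotation_anchor not in ANNOTATION_ANCHORS:
            raise ValueError(f"unknown annotation anchor {self.annotation_anchor!r}")
        if self.query_anchor not in QUERY_ANCHORS:
            raise ValueError(f"unknown query anchor {self.query_anchor!r}")

    @property
    def needs_strand(self) -> bool:
        return self.annotation_anchor in ("five_prime", "three_prime")


@dataclass(frozen=True, slots=True)
class AnchoredDistance:
    """A neighbor's name and its signed anchor-to-anchor distance in bases."""

    annotation_name: str
    signed_distance: int
    region: GenomicRegion | None = None


def resolve_anchor(r: GenomicRegion, anchor: str) -> int:
    """The reference coordinate of one anchor of a region.

    ``start``/``end``/``center`` never consult strand; ``center`` is the
    floor of the mean of the half-open bounds.  ``five_prime`` and
    ``three_prime`` require strand and swap between start and end on the
    minus strand.
    """
    if anchor == "start":
        return r.start
    if anchor == "end":
        return r.end
    if anchor == "center":
        return (r.start + r.end) // 2
    if anchor in ("five_prime", "three_prime"):
        if r.strand is None:
            raise StrandRequiredError(
                f"anchor {anchor!r} needs strand on {r.chrom}:{r.start}-{r.end}"
            )
        if anchor == "five_prime":
            return r.start if r.strand == "+" else r.end
        return r.end if r.strand == "+" else r.start
    raise ValueError(f"unknown anchor {anchor!r}")


def anchored_distance(
    query: GenomicRegion, annotation: GenomicRegion, spec: AnchorSpec
) -> AnchoredDistance:
    """Signed distance annotation-anchor minus query-anchor, same chromosome."""
    if query.chrom != annotation.chrom:
        raise RegionError(
            f"distance undefined across chromosomes "
            f"({query.chrom} vs {annotation.chrom})"
        )
    d = resolve_anchor(annotation, spec.annotation_anchor) - resolve_anchor(
        query, spec.query_anchor
    )
    return AnchoredDistance(annotation.label(), d, annotation)


def distance_annotate(
    index: AnnotationIndex,
    queries: Sequence[GenomicRegion],
    spec: AnchorSpec,
) -> list[tuple[AnchoredDistance | None, AnchoredDistance | None]]:
    """Anchored distance to the left and right neighbor of every query.

    The index must hold stranded annotations whenever the spec uses a
    5'/3' anchor; an unstranded record raises naming the offender.
    """
    if spec.needs_strand:
        for lst in index.per_chrom.values():
            for a in lst:
                if a.strand is None:
                    raise StrandRequiredError(
                        f"annotation {a.label()} ({a.chrom}:{a.start}-{a.end}) "
                        f"lacks strand, required by anchor {spec.annotation_anchor!r}"
                    )
    out: list[tuple[AnchoredDistance | None, AnchoredDistance | None]] = []
    for q, nb in zip(queries, find_neighbors(index, queries)):
        left = anchored_distance(q, nb.left.region, spec) if nb.left else None
        right = anchored_distance(q, nb.right.region, spec) if nb.right else None
        out.append((left, right))
    return out
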