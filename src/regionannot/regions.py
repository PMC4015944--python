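"""Core genomic interval type, coordinate conventions, and the tolerant query parser.

Internally every region is stored in BED-native coordinates: 0-based,
half-open ``[start, end)``.  Position-coordinate input and display
(``chr1:7577506-7577606``) use the 1-based inclusive convention of the
UCSC genome browser; :func:`normalize_region` and :func:`format_region`
convert between the two.

A region with ``start == end`` is a *zero-length element* (an insertion
point, as found in genome-variation data).  In position-coordinate
display a zero-length element is rendered on its raw half-open bounds
with a trailing ``*`` marker (``chr1:500-500*``), because the 1-based
inclusive conversion would otherwise make it indistinguishable from a
one-base region.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "GenomicRegion",
    "PositionRelation",
    "RegionError",
    "RegionParseError",
    "CoordinateError",
    "StrandRequiredError",
    "parse_region_string",
    "normalize_region",
    "compare_positions",
    "format_region",
]


class RegionError(ValueError):
    """Base class for malformed regions or region text."""


class RegionParseError(RegionError):
    """A query or annotation line could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class CoordinateError(RegionError):
    """A coordinate violates the region invariants (negative, end < start)."""


class StrandRequiredError(RegionError):
    """An operation needs strand information that the region does not carry."""


class PositionRelation(Enum):
    """The three possible relations between any two base positions."""

    LESS = -1
    EQUAL = 0
    GREATER = 1

    def flipped(self) -> "PositionRelation":
        """The relation seen from the other operand (LESS <-> GREATER)."""
        return PositionRelation(-self.value)


@dataclass(frozen=True, slots=True)
class GenomicRegion:
    """A chromosome-addressed interval, the unit of queries and annotations.

    Parameters
    ----------
    chrom
        Chromosome label; matched case-insensitively and stored lower-case.
        No prefix aliasing is applied: ``"1"`` and ``"chr1"`` are distinct.
    start, end
        Base offsets with ``0 <= start <= end``.  ``start == end`` denotes
        a zero-length element.
    name
        Optional feature identifier (transcript name, CpG island id, ...).
    strand
        ``"+"``, ``"-"`` or ``None``.  Only distance anchoring uses it.
    raw_coords
        Set by the parser when the printed coordinates are already
        half-open (the ``*`` zero-length marker); ignored in comparisons.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None
    raw_coords: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", self.chrom.lower())
        if self.start < 0:
            raise CoordinateError(f"negative start {self.start} in {self.chrom}")
        if self.end < self.start:
            raise CoordinateError(
                f"end {self.end} precedes start {self.start} on {self.chrom}"
            )
        if self.strand not in (None, "+", "-"):
            raise RegionError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_zero_length(self) -> bool:
        return self.start == self.end

    def sort_key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.name or "")

    def label(self) -> str:
        """The name if set, else the positions-style display string."""
        return self.name if self.name else format_region(self, "positions")


def compare_positions(a: int, b: int) -> PositionRelation:
    """Classify the relation between two base positions.

    Exactly one of LESS, EQUAL, GREATER for any pair of offsets.
    """
    if a < b:
        return PositionRelation.LESS
    if a > b:
        return PositionRelation.GREATER
    return PositionRelation.EQUAL


_INT_RE = re.compile(r"[0-9][0-9,]*$")
# chrom [: or space] start [- or space] end [optional zero-length marker]
_POSITION_RE = re.compile(
    r"^(?P<chrom>[^\s:]+)\s*[:\s]\s*(?P<start>[0-9][0-9,]*)"
    r"\s*[-\s]\s*(?P<end>[0-9][0-9,]*)\s*(?P<marker>\*)?$"
)


def _to_int(token: str) -> int:
    return int(token.replace(",", ""))


def parse_region_string(text: str, line_number: int | None = None) -> GenomicRegion:
    """Parse one query line in any accepted dialect.

    Accepted spellings (case-insensitive chromosome, optional thousands
    separators in the coordinates):

    * ``chr1:7577506-7577606`` — colon/minus position coordinates;
    * ``Chr2:7,577,506-7,577,606`` — with thousands separators;
    * ``CHR3 7577506 7,577,606`` — whitespace or tab separated, e.g.
      pasted from a spreadsheet; extra BED columns (name, score, strand)
      are kept when present.

    Coordinates are returned **as printed**; converting them to the
    internal 0-based half-open convention is :func:`normalize_region`'s
    job.  A trailing ``*`` marks a zero-length element whose printed
    bounds are already half-open.
    """
    s = text.strip()
    if not s:
        raise RegionParseError("empty line", line_number)

    fields = s.split()
    if len(fields) >= 3 and _INT_RE.match(fields[1]) and _INT_RE.match(fields[2]):
        chrom = fields[0]
        start, end = _to_int(fields[1]), _to_int(fields[2])
        name = fields[3] if len(fields) >= 4 else None
        strand = None
        if len(fields) >= 6 and fields[5] in ("+", "-"):
            strand = fields[5]
        try:
            return GenomicRegion(chrom, start, end, name=name, strand=strand)
        except CoordinateError as exc:
            raise RegionParseError(str(exc), line_number) from exc

    m = _POSITION_RE.match(s)
    if m is None:
        raise RegionParseError(f"unrecognized region {s!r}", line_number)
    start, end = _to_int(m.group("start")), _to_int(m.group("end"))
    marker = m.group("marker") is not None
    if marker and start != end:
        raise RegionParseError(
            f"zero-length marker on a non-zero-length region {s!r}", line_number
        )
    try:
        return GenomicRegion(m.group("chrom"), start, end, raw_coords=marker)
    except CoordinateError as exc:
        raise RegionParseError(str(exc), line_number) from exc


def normalize_region(r: GenomicRegion, convention: str) -> GenomicRegion:
    """Convert a freshly parsed region to the internal 0-based half-open form.

    ``convention="bed"`` passes through unchanged (BED is already 0-based
    half-open).  ``convention="positions"`` converts 1-based inclusive
    input by ``start := start - 1`` — except for regions the parser
    flagged as already half-open (the ``*`` zero-length display form).
    """
    if convention == "bed":
        return r
    if convention != "positions":
        raise ValueError(f"unknown coordinate convention {convention!r}")
    if r.raw_coords:
        return GenomicRegion(r.chrom, r.start, r.end, name=r.name, strand=r.strand)
    if r.start < 1:
        raise CoordinateError(
            f"1-based position coordinates must start at 1 or more, got {r.start}"
        )
    return GenomicRegion(r.chrom, r.start - 1, r.end, name=r.name, strand=r.strand)


def format_region(r: GenomicRegion, convention: str) -> str:
    """Render a region as text.

    ``bed`` renders the tab-separated BED columns (name/strand appended
    when present).  ``positions`` renders ``chrN:start-end`` in 1-based
    inclusive display coordinates; zero-length elements render on their
    raw half-open bounds with the ``*`` marker so that
    ``normalize ∘ parse ∘ format`` is the identity.
    """
    if convention == "bed":
        cols = [r.chrom, str(r.start), str(r.end)]
        if r.name is not None or r.strand is not None:
            cols.append(r.name if r.name is not None else ".")
        if r.strand is not None:
            cols.extend(["0", r.strand])
        return "\t".join(cols)
    if convention != "positions":
        raise ValueError(f"unknown coordinate convention {convention!r}")
    if r.is_zero_length:
        return f"{r.chrom}:{r.start}-{r.end}*"
    return f"{r.chrom}:{r.start + 1}-{r.end}"
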