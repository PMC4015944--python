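"""Readers and writers: BED / custom-column annotation files, query files,
the tab-delimited output table with "//"-joined hits and UCSC links, and
annotation-preparation helpers (promoter construction, file sorting).
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from .regions import (
    GenomicRegion,
    RegionParseError,
    StrandRequiredError,
    format_region,
    normalize_region,
    parse_region_string,
)

__all__ = [
    "ColumnMapping",
    "BED_MAPPING",
    "DISTANCE_MAPPING",
    "OutputRow",
    "HIT_SEPARATOR",
    "read_annotation_file",
    "read_query_file",
    "write_output_table",
    "write_bed",
    "ucsc_link",
    "make_promoters",
    "sort_annotation_file",
    "join_hits",
]

#: Separator between multiple hits within one output cell.
HIT_SEPARATOR = "//"

_SKIP_PREFIXES = ("#", "track", "browser")


@dataclass(frozen=True, slots=True)
class ColumnMapping:
    """1-based column indices locating the region fields in a delimited file.

    ``name_col`` may point past the end of short lines (a plain 3-column
    BED file with the default mapping yields unnamed regions); the
    chromosome/start/end columns — and the strand column when set — are
    mandatory on every data line.
    """

    chrom_col: int = 1
    start_col: int = 2
    end_col: int = 3
    name_col: int = 4
    strand_col: int | None = None

    def __post_init__(self) -> None:
        idx = [self.chrom_col, self.start_col, self.end_col, self.name_col]
        if self.strand_col is not None:
            idx.append(self.strand_col)
        if any(i < 1 for i in idx):
            raise ValueError("column indices are 1-based and must be positive")
        if len(set(idx)) != len(idx):
            raise ValueError(f"column indices must be pairwise distinct: {idx}")


BED_MAPPING = ColumnMapping()
#: The 5-column stranded format "Chromosome start end strand annotation".
DISTANCE_MAPPING = ColumnMapping(chrom_col=1, start_col=2, end_col=3,
                                 name_col=5, strand_col=4)


@dataclass(frozen=True, slots=True)
class OutputRow:
    """One annotated query: display string, UCSC link, one cell per source."""

    query_display: str
    link: str
    cells: tuple[str, ...]


def _data_lines(path: str | os.PathLike) -> Iterable[tuple[int, str]]:
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            stripped = line.strip()
            if not stripped or stripped.lower().startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def _parse_mapped_line(
    line: str, lineno: int, mapping: ColumnMapping, path: str
) -> GenomicRegion:
    fields = line.split()
    needed = max(mapping.chrom_col, mapping.start_col, mapping.end_col)
    if mapping.strand_col is not None:
        needed = max(needed, mapping.strand_col)
    if len(fields) < needed:
        raise RegionParseError(
            f"{path}: expected at least {needed} columns, got {len(fields)}", lineno
        )
    try:
        start = int(fields[mapping.start_col - 1].replace(",", ""))
        end = int(fields[mapping.end_col - 1].replace(",", ""))
    except ValueError as exc:
        raise RegionParseError(f"{path}: non-integer coordinate", lineno) from exc
    name = None
    if len(fields) >= mapping.name_col:
        name = fields[mapping.name_col - 1]
        if HIT_SEPARATOR in name:
            raise RegionParseError(
                f"{path}: annotation name {name!r} contains the reserved "
                f"separator {HIT_SEPARATOR!r}", lineno,
            )
    strand = None
    if mapping.strand_col is not None:
        token = fields[mapping.strand_col - 1]
        if token in ("+", "-"):
            strand = token
        elif token != ".":
            raise RegionParseError(f"{path}: unknown strand symbol {token!r}", lineno)
    try:
        return GenomicRegion(fields[mapping.chrom_col - 1], start, end,
                             name=name, strand=strand)
    except ValueError as exc:
        raise RegionParseError(f"{path}: {exc}", lineno) from exc


def read_annotation_file(
    path: str | os.PathLike, mapping: ColumnMapping = BED_MAPPING
) -> list[GenomicRegion]:
    """Read an annotation file with user-specified column indices.

    Coordinates are taken as BED-convention (0-based half-open).  Track,
    browser and ``#`` comment lines are skipped; errors report the file
    and line number.
    """
    return [
        _parse_mapped_line(line, lineno, mapping, str(path))
        for lineno, line in _data_lines(path)
    ]


def read_query_file(
    path: str | os.PathLike, coords: str = "auto"
) -> tuple[list[GenomicRegion], list[str]]:
    """Read query regions, one per line, in any accepted dialect.

    ``coords`` is the coordinate convention of the input: ``"bed"``
    (0-based half-open), ``"positions"`` (1-based inclusive), or
    ``"auto"``, which treats 3+-column tabular lines as BED and
    ``chrom:start-end`` lines as position coordinates.  Duplicated lines
    are preserved and annotated independently.  Returns the normalized
    regions and the original line texts (for input-order-compatible
    output).
    """
    regions: list[GenomicRegion] = []
    displays: list[str] = []
    for lineno, line in _data_lines(path):
        r = parse_region_string(line, lineno)
        if coords == "auto":
            convention = "bed" if len(line.split()) >= 3 else "positions"
        else:
            convention = coords
        try:
            regions.append(normalize_region(r, convention))
        except ValueError as exc:
            raise RegionParseError(f"{path}: {exc}", lineno) from exc
        displays.append(line.strip())
    return regions, displays


def join_hits(names: Iterable[str]) -> str:
    """Join multiple hit names for one output cell; empty iterable → empty cell."""
    return HIT_SEPARATOR.join(names)


def write_output_table(
    rows: Sequence[OutputRow],
    destination: str | os.PathLike | IO[str],
    columns: Sequence[str],
    include_header: bool = True,
    compress: bool = False,
) -> None:
    """Write the tab-delimited annotation table.

    One line per query in input order (duplicates included), a header
    line naming the region, link and per-source columns (suppressible
    for pipe-friendliness), and multiple hits within a cell joined by
    ``"//"``.  ``compress=True`` gzip-compresses the output file.
    """
    own = False
    if hasattr(destination, "write"):
        fh = destination
    else:
        own = True
        if compress:
            fh = gzip.open(destination, "wt", encoding="utf-8")
        else:
            fh = open(destination, "wt", encoding="utf-8")
    try:
        if include_header:
            fh.write("\t".join(["region", "link", *columns]) + "\n")
        for row in rows:
            fh.write("\t".join([row.query_display, row.link, *row.cells]) + "\n")
    finally:
        if own:
            fh.close()


def write_bed(regions: Iterable[GenomicRegion], path: str | os.PathLike) -> None:
    """Write regions as BED lines (name/score/strand columns when present)."""
    with open(path, "wt", encoding="utf-8") as fh:
        for r in regions:
            fh.write(format_region(r, "bed") + "\n")


def ucsc_link(r: GenomicRegion, assembly: str) -> str:
    """Hyperlink displaying the region in the UCSC genome browser.

    The position parameter uses 1-based inclusive display coordinates;
    zero-length elements use their raw half-open bounds (marker omitted,
    the browser centers on the insertion point).
    """
    if not assembly:
        raise ValueError("assembly label must be non-empty")
    if r.is_zero_length:
        pos = f"{r.chrom}:{r.start}-{r.end}"
    else:
        pos = f"{r.chrom}:{r.start + 1}-{r.end}"
    return f"https://genome.ucsc.edu/cgi-bin/hgTracks?db={assembly}&position={pos}"


def make_promoters(
    transcripts: Iterable[GenomicRegion], halfwidth: int = 1000
) -> list[GenomicRegion]:
    """Build promoter regions around each transcript's TSS.

    The TSS is the transcript start on the plus strand and the end on
    the minus strand; the promoter spans ``halfwidth`` bases (1 kb by
    default) upstream and downstream of it, clamped at coordinate 0.
    The transcript's name and strand are inherited.
    """
    out = []
    for t in transcripts:
        if t.strand is None:
            raise StrandRequiredError(
                f"transcript {t.label()} ({t.chrom}:{t.start}-{t.end}) has no "
                "strand; the TSS is strand-dependent"
            )
        tss = t.start if t.strand == "+" else t.end
        out.append(
            GenomicRegion(t.chrom, max(0, tss - halfwidth), tss + halfwidth,
                          name=t.name, strand=t.strand)
        )
    return out


def sort_annotation_file(
    in_path: str | os.PathLike,
    out_path: str | os.PathLike,
    mapping: ColumnMapping = BED_MAPPING,
) -> None:
    """Rewrite an annotation file with data lines sorted by (chrom, start, end).

    Line content is unchanged; comment/track lines are kept at the top
    in their original order.  Sorting an already-sorted file is the
    identity.
    """
    header: list[str] = []
    data: list[tuple[tuple, str]] = []
    with open(in_path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            stripped = line.strip()
            if not stripped or stripped.lower().startswith(_SKIP_PREFIXES):
                header.append(line)
                continue
            r = _parse_mapped_line(line, lineno, mapping, str(in_path))
            data.append(((r.chrom, r.start, r.end), line))
    data.sort(key=lambda kv: kv[0])
    with open(out_path, "wt", encoding="utf-8") as fh:
        for line in header:
            fh.write(line + "\n")
        for _, line in data:
            fh.write(line + "\n")
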