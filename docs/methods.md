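# Methods

## Coordinate conventions

All regions are stored 0-based half-open (`[start, end)`), the native
BED convention, which makes every interval computation directly
comparable to standard interval toolkits. Two input conventions are
supported at the boundary:

* **BED input** (tabular, 3+ columns) passes through unchanged.
* **Position coordinates** (`chr1:7577506-7577606`) are read as 1-based
  inclusive — the UCSC browser convention — and converted by
  `start := start − 1`. The accepted dialects are case-insensitive
  chromosome labels, optional thousands separators, and colon/minus or
  whitespace/tab separators interchangeably, so coordinates can be
  pasted straight from a spreadsheet.

Chromosome labels are lower-cased on ingest and matched exactly
otherwise; `1` and `chr1` are deliberately distinct because no aliasing
rule is universally safe. Coordinates are not validated against
chromosome lengths (lengths are not an input anywhere in the pipeline).

**Zero-length elements** (`start == end`) model insertion points from
genome-variation data. In positions display they are rendered on their
raw half-open bounds with a trailing `*` (`chr1:500-500*`): applying
the 1-based inclusive conversion would produce `end < start`, and
without a marker the display would be indistinguishable from a one-base
region. The parser consumes the marker and flags the region so that
`normalize ∘ parse ∘ format` is the identity for every region,
zero-length included. UCSC links drop the marker (the browser treats
`chr1:500-500` as a centering hint).

## Overlap predicate and taxonomy

Proper intervals overlap iff their half-open intersection is non-empty;
abutting intervals do not overlap. A zero-length element at `p`
overlaps a proper `[s, e)` iff `s ≤ p ≤ e` (boundary-inclusive: an
insertion point sitting on either edge touches the feature); two
zero-length elements overlap iff they coincide. This is the unique
natural combination under which exhaustive enumeration of all start/end
placements yields exactly 16 overlap configuration classes
(9 proper/proper + 3 point-query + 3 point-annotation + 1 both-point);
making the zero-length rule boundary-exclusive collapses six of them,
making the proper rule closed adds abutting pseudo-overlaps. The class
table, its canonical numbering and the two flag-resolved pattern
collisions are documented in `overlap_classes.md`. `enumerate_overlap_classes`
re-derives the table by brute force over a small grid; any grid of at
least 5 positions realizes every class, and the test suite checks
stability for grids 5–10.

Overlap and neighbor queries ignore strand; strand only enters distance
anchoring.

## Annotation engine

Annotations are partitioned per chromosome and sorted by
`(start, end, name)`; duplicates are retained. Overlap queries run as a
sweep: queries are sorted internally by `(chromosome, start)` and a
memoized cursor per chromosome advances past the front of the sorted
list while the front annotation's end precedes the current query's
start — such an annotation can never overlap the current or any later
query of the batch. The cursor never skips interior annotations: long
annotations that span many queries stay in the scan window (bounded by
`annotation.start ≤ query.end`) until truly dead, which keeps the sweep
exactly equal to the all-pairs definition. Results are re-ordered to
the caller's input order, so duplicated queries are annotated
independently and output can be pasted side-by-side with input.

Neighbors are the closest non-overlapping annotation per side,
formalized as **maximal end at or before the query start** (left) and
**minimal start at or after the query end** (right) — the only reading
under which the left distance `q.start − a.end` and right distance
`a.start − q.end` are always non-negative. Ties are broken
deterministically: left by (max end, max start, smallest name), right
by (min start, min end, smallest name); exactly one neighbor per side
is reported. Implementation is binary search on two sorted views (by
start and by end); the by-end view is what makes the nested-annotation
case correct, where the last-by-start annotation is not the one ending
closest to the query. Abutting proper annotations are neighbors at
distance 0; a zero-length annotation sitting exactly on a query
boundary overlaps it (per the taxonomy) and is therefore never a
neighbor.

## Distances

A distance is `anchor(annotation) − anchor(query)`, signed on the
reference strand: positive means the annotation anchor lies at a larger
reference coordinate. Anchors: `start`, `end` (the half-open bounds,
used directly so results are bit-exactly reproducible), `center`
(`floor((start + end) / 2)`, strand-independent by construction), and
`five_prime`/`three_prime`, which map to start/end on the plus strand
and end/start on the minus strand and therefore require strand.
Distance mode reports both neighbors rather than the nearer one —
signed output to both sides preserves strictly more information and
the caller can trivially take the smaller magnitude. Distances to
*overlapping* annotations are not computed; overlaps are reported by
the overlap query.

Promoters are built as `[TSS − 1000, TSS + 1000)` around each
transcript's TSS (start on `+`, end on `−`), 1 kb up- and downstream,
clamped at coordinate 0 only; the transcript's name and strand are
inherited. The half-width is a parameter (`halfwidth`, bases, default
1000).

## Output table

Tab-delimited, one row per query in input order, one header line
(suppressible), a UCSC browser hyperlink per region, and one column per
annotation source (plus `:left`/`:right` columns when neighbors are
requested). Multiple hits in a cell are joined by the literal `//`;
annotation names containing `//` are rejected at ingest so the table
re-parses unambiguously. With `--first-hit-only` the first hit in
`(start, end, name)` order is kept. The interactive result filtering of
a GUI is out of scope; the table is designed to be filtered with
`grep`/`awk` or a spreadsheet instead, and output files ending in `.gz`
are gzip-compressed.

## Synthetic fixtures and the oracle

The generator scatters regions uniformly over `n_chromosomes`
chromosomes of `chrom_length` bases with lengths uniform in
`[min_length, max_length]` and an exact fraction of zero-length
elements, fully determined by the seed. Defaults (5 chromosomes of
1 Mb, lengths 1–1000, 5% zero-length) emulate a dense peak-annotation
workload where boundary cases actually occur; query-set sizes in the
tests sweep 10 to 100,000 against 1 or 10 annotation sources, the shape
of a realistic batch-annotation benchmark, with per-source annotation
counts (50–20,000) chosen so the all-pairs oracle stays desk-feasible.
What the fixtures do *not* emulate: chromosome-specific length
distributions, clustered/overlapping feature structure of real gene
models, or real chromosome counts — so passing tests demonstrate
algorithmic correctness of the interval logic, not biological realism
of any annotation set.

The oracle answers every query by scanning all annotations with no
index, restating the overlap predicate and neighbor tie-breaks from
their definitions in vectorized NumPy; it shares only the region type
with the engine, so an engine predicate bug cannot validate itself. The
`benchmark_protocol` harness runs both implementations on identical
fixtures, asserts exact equality, and reports wall-clock times for
documentation only — timings are hardware-dependent and no absolute or
relative timing is asserted beyond a deliberately generous
subquadratic-growth sanity bound (a 16× larger query set must cost
less than 120× the time, where quadratic growth would be 256×).

## Degenerate inputs and numerical choices

Empty annotation sets build a valid index and yield empty hit lists and
absent neighbors; queries on chromosomes absent from the index get
empty results rather than errors. All tie-breaks (sorting, neighbor
selection, first-hit truncation) are lexicographic and deterministic,
so repeated runs are byte-identical. Unnamed regions sort with the
empty name and are displayed by their position string.

## Known limitations

* No liftover, no chromosome-length clamping of promoters at the right
  end (lengths are not an input), no GFF/GTF/VCF ingestion — annotation
  files are BED or user-mapped delimited text.
* One neighbor per side; equally-near alternates beyond the documented
  tie-break are not reported.
* The registry is a plain local file mapping (release, genome, name) to
  paths; fetching or updating annotation collections is out of scope.
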