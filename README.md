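# regionannot

Annotate sets of genomic regions — ChIP-seq peaks, DNase hypersensitive
sites, methylation windows, variant insertion points — with the known
features that overlap them or sit next to them: transcripts, CpG
islands, promoters, or any user-supplied BED track. `regionannot` is a
library plus a small command-line tool for the question every genomics
analysis asks first: *what is at these coordinates?*

## The model

Two regions on the same chromosome are compared through the three
possible relations (`<`, `=`, `>`) between their start and end
positions. From the four cross-comparisons

```
(q.start vs a.start,  q.start vs a.end,  q.end vs a.start,  q.end vs a.end)
```

follow exactly **16 realizable overlap configurations** once zero-length
elements (insertion points, `start == end`) are admitted: 9 Allen-style
relations between two proper intervals with a non-empty half-open
intersection, 3 configurations of a point query against a proper
annotation, 3 of a point annotation against a proper query, and 1 of
two coincident points. The full table with ASCII diagrams is in
[docs/overlap_classes.md](docs/overlap_classes.md) and, machine-readable,
in `regionannot.CLASS_TABLE`.

A **neighbor** is the closest annotation that does *not* overlap the
query — closest meaning no other annotation lies between, not smallest
physical distance: the left neighbor maximizes its end at or before the
query start, the right neighbor minimizes its start at or after the
query end. Left distance = query start − annotation end; right
distance = annotation start − query end.

Annotation proceeds by a sorted sweep: annotations are held per
chromosome sorted by start position, queries are sorted internally by
start, and a memoized cursor per chromosome skips annotations that can
no longer overlap any later query. Results come back in input order,
duplicated queries included, and are exactly equal to the all-pairs
definition (the test suite asserts this against an independent
brute-force oracle on 20 seeded fixture grids up to 100,000 × 20,000
regions).

**Distance mode** measures signed distances between configurable
anchors: the annotation's 5' end, 3' end, start, end, or center against
the query's start, end, or center. The 5' end is the start base on the
plus strand and the end base on the minus strand (vice versa for 3'),
so distance-mode annotations carry strand. Positive means the
annotation anchor lies downstream (larger reference coordinate) of the
query anchor.

Coordinates are internally 0-based half-open (BED-native). Pasted
position coordinates (`chr1:7577506-7577606`, case-insensitive, with or
without thousands separators, colon/minus or whitespace separators) are
read as 1-based inclusive, the UCSC browser convention.

## Worked example

Annotate two duplicated TP53-promoter-region queries and one upstream
control region against a small gene track:

```sh
$ cat queries.txt
chr17:7577506-7577606
chr17:7577506-7577606
chr17:7400001-7400100

$ cat genes.bed
chr17	7565097	7590856	TP53	0	-
chr17	7573931	7595551	WRAP53	0	+
chr17	7210000	7250000	GRIN2C	0	-

$ regionannot custom queries.txt -a genes.bed --neighbors --genome hg19 --quiet -o out.tsv
$ cut -f1,3- out.tsv
region	genes.bed	genes.bed:left	genes.bed:right
chr17:7577506-7577606	TP53//WRAP53	GRIN2C(327505)
chr17:7577506-7577606	TP53//WRAP53	GRIN2C(327505)
chr17:7400001-7400100		GRIN2C(150000)	TP53(164997)
```

The first query overlaps both TP53 and WRAP53 — multiple hits are
joined by `//` — and is listed twice because duplicated queries are
annotated independently. The control region overlaps nothing; its
nearest non-overlapping features are GRIN2C 150,000 bases to the left
(gap measured from query start to annotation end) and TP53 164,997
bases to the right. The omitted second column holds a UCSC genome
browser link for each region.

Distance mode, measuring from each query start to the 5' end (TSS) of
the neighboring genes:

```sh
$ regionannot distance queries.txt -a tss.txt --annotation-anchor five_prime \
      --query-anchor start --quiet | cut -f1,3-
region	tss.txt:left	tss.txt:right
chr17:7577506-7577606	GRIN2C(-327505)
chr17:7577506-7577606	GRIN2C(-327505)
chr17:7400001-7400100	GRIN2C(-150000)	TP53(+190856)
```

GRIN2C is on the minus strand, so its 5' end is its *end* coordinate;
the sign says the TSS lies upstream (−) or downstream (+) of the query
start on the reference.

The third subcommand, `regionannot annotate`, runs the same pipeline
against annotation sources listed in a registry file (whitespace-
separated columns: release, genome, annotation name, path, optional
column indices), so frequently used tracks can be kept in one place:

```sh
regionannot annotate queries.txt --registry registry.tsv --genome hg19 \
    --annotation refseq.bed --annotation cpg.bed --neighbors -o out.tsv
```

Library use mirrors the CLI:

```python
from regionannot import build_index, find_overlaps, classify_overlap

index = build_index(annotations, "refseq")
hits = find_overlaps(index, queries)          # per-query, input order
cls = classify_overlap(queries[0], hits[0][0])  # one of the 16 classes
```

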