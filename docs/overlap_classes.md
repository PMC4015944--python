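# The 16 overlap configuration classes

A query region (`#`) and an annotation region (`=`) on the same
chromosome are classified by the four cross-comparisons between their
start/end positions,

```
pattern = (q.start vs a.start, q.start vs a.end, q.end vs a.start, q.end vs a.end)
```

with each comparison one of `L` (less), `E` (equal), `G` (greater),
plus two flags marking zero-length participants (`|`, an insertion
point with `start == end`).

Overlap convention: two proper intervals overlap iff their half-open
intersection is non-empty (abutting intervals do not overlap); a
zero-length element overlaps a proper interval when it lies on or
between its boundaries; two zero-length elements overlap when they
coincide. Under this convention exhaustive enumeration of all start/end
placements realizes exactly the 16 classes below — 9 for proper pairs,
7 involving zero-length elements — and no others.

Class ids are canonical repo numbering: proper/proper 1–9, zero-length
query 10–12, zero-length annotation 13–15, both zero-length 16; within
each group patterns are sorted with L < E < G. The machine-readable
form is `regionannot.CLASS_TABLE`.

| id | name | pattern | q point | a point | diagram |
|----|------|---------|---------|---------|---------|
| 1 | left-overlap | L,L,G,L | | | `####` over `..====` |
| 2 | finished-by | L,L,G,E | | | `######` over `..====` |
| 3 | contains | L,L,G,G | | | `########` over `..====` |
| 4 | starts | E,L,G,L | | | `####` over `========` |
| 5 | equals | E,L,G,E | | | `####` over `====` |
| 6 | started-by | E,L,G,G | | | `########` over `====` |
| 7 | during | G,L,G,L | | | `..####` over `========` |
| 8 | finishes | G,L,G,E | | | `..####` over `======` |
| 9 | right-overlap | G,L,G,G | | | `..####` over `====` |
| 10 | point-query-at-annotation-start | E,L,E,L | ✓ | | `\|` over `====` |
| 11 | point-query-inside | G,L,G,L | ✓ | | `.\|` over `====` |
| 12 | point-query-at-annotation-end | G,E,G,E | ✓ | | `....\|` over `====` |
| 13 | point-annotation-at-query-end | L,L,E,E | | ✓ | `####` over `....\|` |
| 14 | point-annotation-inside | L,L,G,G | | ✓ | `####` over `.\|` |
| 15 | point-annotation-at-query-start | E,E,G,G | | ✓ | `####` over `\|` |
| 16 | coincident-points | E,E,E,E | ✓ | ✓ | `\|` over `\|` |

Two pattern collisions are resolved by the point flags: class 11 shares
the pattern of class 7 (`during`) and class 14 shares the pattern of
class 3 (`contains`); the `(pattern, q_is_point, a_is_point)` triple is
unique.

The non-overlap configurations — disjoint intervals, abutting proper
intervals, distinct points — are deliberately outside the taxonomy:
those annotations are reported by the *neighbor* query instead, and a
region can never be both an overlap hit and a neighbor of the same
query.
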