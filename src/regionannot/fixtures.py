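"""Synthetic region generators and the all-pairs oracle used to validate the engine.

The generator emulates the shape of real annotation workloads: regions
scattered uniformly over a handful of chromosomes, lengths drawn from a
bounded range, and an exact fraction of zero-length elements (insertion
points).  Everything is deterministic under the seed.

The oracle answers overlap and neighbor queries by evaluating *every*
query-annotation pair with no index.  It deliberately restates the
overlap predicate and the neighbor tie-breaks from their definitions —
in NumPy, sharing no code with the engine beyond the region type — so a
predicate bug in the engine cannot validate itself.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .regions import GenomicRegion

__all__ = [
    "FixtureSpec",
    "generate_regions",
    "oracle_overlaps",
    "oracle_neighbors",
    "benchmark_protocol",
]


@dataclass(frozen=True, slots=True)
class FixtureSpec:
    """Parameters of one synthetic region set.

    Defaults mimic a desk-scale annotation workload: a few chromosomes
    of 1 Mb, feature lengths up to 1 kb, and 5% zero-length elements so
    every boundary rule is exercised.
    """

    n_regions: int
    n_chromosomes: int = 5
    chrom_length: int = 1_000_000
    min_length: int = 1
    max_length: int = 1000
    zero_length_fraction: float = 0.05
    seed: int = 0
    stranded: bool = False
    named: bool = True


def generate_regions(spec: FixtureSpec) -> list[GenomicRegion]:
    """Generate a reproducible random region set.

    Starts are uniform over each chromosome, lengths uniform over
    ``[min_length, max_length]``, and exactly
    ``round(zero_length_fraction * n_regions)`` regions are zero-length.
    Identical spec (including seed) always yields the identical list.
    """
    n = spec.n_regions
    if n == 0:
        return []
    rng = np.random.default_rng(spec.seed)
    chrom_idx = rng.integers(0, spec.n_chromosomes, size=n)
    starts = rng.integers(0, spec.chrom_length, size=n)
    lengths = rng.integers(spec.min_length, spec.max_length + 1, size=n)
    n_zero = int(round(spec.zero_length_fraction * n))
    zero_at = rng.permutation(n)[:n_zero]
    lengths[zero_at] = 0
    strands = rng.integers(0, 2, size=n) if spec.stranded else None
    out = []
    for i in range(n):
        out.append(
            GenomicRegion(
                f"chr{chrom_idx[i] + 1}",
                int(starts[i]),
                int(starts[i] + lengths[i]),
                name=f"r{i:06d}" if spec.named else None,
                strand=("+-"[strands[i]] if strands is not None else None),
            )
        )
    return out


# --- all-pairs oracle -------------------------------------------------------
#
# Overlap predicate, restated from its definition for arrays of
# annotations against one query (proper: half-open intersection;
# zero-length element vs proper interval: boundary-inclusive; two
# zero-length elements: coincidence).


def _group_by_chrom(regions: Sequence[GenomicRegion]):
    groups: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        groups.setdefault(r.chrom, []).append(i)
    return groups


class _ChromArrays:
    def __init__(self, regions: Sequence[GenomicRegion]):
        # annotation output order is (start, end, name)
        order = sorted(range(len(regions)),
                       key=lambda i: (regions[i].start, regions[i].end,
                                      regions[i].name or ""))
        self.regions = [regions[i] for i in order]
        self.starts = np.array([r.start for r in self.regions], dtype=np.int64)
        self.ends = np.array([r.end for r in self.regions], dtype=np.int64)
        self.proper = self.ends > self.starts

    def overlap_mask(self, q: GenomicRegion) -> np.ndarray:
        s, e, proper = self.starts, self.ends, self.proper
        if q.start < q.end:
            return np.where(
                proper,
                (s < q.end) & (e > q.start),
                (s >= q.start) & (s <= q.end),
            )
        p = q.start
        return np.where(proper, (s <= p) & (e >= p), s == p)


def oracle_overlaps(
    queries: Sequence[GenomicRegion], annotations: Sequence[GenomicRegion]
) -> list[list[GenomicRegion]]:
    """All-pairs overlap evaluation, results in (start, end, name) order."""
    by_chrom = {
        chrom: _ChromArrays([annotations[i] for i in idx])
        for chrom, idx in _group_by_chrom(annotations).items()
    }
    results: list[list[GenomicRegion]] = []
    for q in queries:
        arr = by_chrom.get(q.chrom)
        if arr is None:
            results.append([])
            continue
        mask = arr.overlap_mask(q)
        results.append([arr.regions[j] for j in np.nonzero(mask)[0]])
    return results


def _pick_left(arr: _ChromArrays, q: GenomicRegion, mask: np.ndarray):
    """Maximal end, then maximal start, then smallest name."""
    cand = np.nonzero((arr.ends <= q.start) & ~mask)[0]
    if cand.size == 0:
        return None
    ends = arr.ends[cand]
    cand = cand[ends == ends.max()]
    starts = arr.starts[cand]
    cand = cand[starts == starts.max()]
    best = min(cand, key=lambda j: arr.regions[j].name or "")
    return arr.regions[best], q.start - arr.regions[best].end


def _pick_right(arr: _ChromArrays, q: GenomicRegion, mask: np.ndarray):
    """Minimal start, then minimal end, then smallest name."""
    cand = np.nonzero((arr.starts >= q.end) & ~mask)[0]
    if cand.size == 0:
        return None
    starts = arr.starts[cand]
    cand = cand[starts == starts.min()]
    ends = arr.ends[cand]
    cand = cand[ends == ends.min()]
    best = min(cand, key=lambda j: arr.regions[j].name or "")
    return arr.regions[best], arr.regions[best].start - q.end


def oracle_neighbors(
    queries: Sequence[GenomicRegion], annotations: Sequence[GenomicRegion]
) -> list[tuple]:
    """All-pairs neighbor evaluation.

    Returns per query a ``(left, right)`` pair where each side is either
    ``None`` or ``(region, distance)``; distances follow the left =
    query-start minus annotation-end, right = annotation-start minus
    query-end conventions.
    """
    by_chrom = {
        chrom: _ChromArrays([annotations[i] for i in idx])
        for chrom, idx in _group_by_chrom(annotations).items()
    }
    results = []
    for q in queries:
        arr = by_chrom.get(q.chrom)
        if arr is None:
            results.append((None, None))
            continue
        mask = arr.overlap_mask(q)
        results.append((_pick_left(arr, q, mask), _pick_right(arr, q, mask)))
    return results


def benchmark_protocol(
    sizes: Sequence[int],
    n_sources: int = 1,
    seed: int = 0,
    n_annotations: int = 10_000,
    timer: Callable[[], float] = time.perf_counter,
) -> list[dict]:
    """Run engine and oracle on identical fixtures across a size sweep.

    For each query-set size, generates the queries and ``n_sources``
    annotation sets, runs both implementations, asserts their results
    are identical, and records wall-clock times.  The timings are for
    documentation only — correctness equality is the assertion.
    """
    from .engine import build_index, find_neighbors, find_overlaps

    rows = []
    for k, size in enumerate(sizes):
        queries = generate_regions(FixtureSpec(size, seed=seed + 1000 * k))
        sources = [
            generate_regions(
                FixtureSpec(n_annotations, seed=seed + 1000 * k + 1 + s)
            )
            for s in range(n_sources)
        ]
        t0 = timer()
        engine_out = []
        for anns in sources:
            index = build_index(anns)
            engine_out.append(
                (find_overlaps(index, queries), find_neighbors(index, queries))
            )
        t_engine = timer() - t0

        t0 = timer()
        oracle_out = [
            (oracle_overlaps(queries, anns), oracle_neighbors(queries, anns))
            for anns in sources
        ]
        t_oracle = timer() - t0

        for (e_ov, e_nb), (o_ov, o_nb) in zip(engine_out, oracle_out):
            if e_ov != o_ov:
                raise AssertionError(f"overlap mismatch at size {size}")
            for enb, onb in zip(e_nb, o_nb):
                e_pair = (
                    (enb.left.region, enb.left.distance) if enb.left else None,
                    (enb.right.region, enb.right.distance) if enb.right else None,
                )
                if e_pair != onb:
                    raise AssertionError(f"neighbor mismatch at size {size}")
        rows.append(
            {
                "size": size,
                "n_sources": n_sources,
                "engine_time": t_engine,
                "oracle_time": t_oracle,
            }
        )
    return rows
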