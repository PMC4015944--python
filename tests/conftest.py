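"""Shared helpers for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import settings

from regionannot import GenomicRegion
from regionannot.fixtures import FixtureSpec, generate_regions

settings.register_profile("suite", derandomize=True, max_examples=200)
settings.load_profile("suite")


def adversarial_set(n: int, seed: int, **kw) -> list[GenomicRegion]:
    """A random region set spiked with the known hard cases.

    Adds duplicates of the first few generated regions plus crafted
    nested and abutting configurations, so every fixture exercises
    duplicate handling, nested-annotation neighbor logic, zero-length
    boundaries and abutting intervals.
    """
    regions = generate_regions(FixtureSpec(n, seed=seed, **kw))
    spiked = list(regions)
    spiked.extend(regions[: max(1, n // 50)])  # exact duplicates
    spiked.extend(
        [
            GenomicRegion("chr1", 100, 500, name="outer"),   # long, nested pair
            GenomicRegion("chr1", 200, 210, name="inner"),
            GenomicRegion("chr1", 500, 600, name="abut"),    # abuts "outer"
            GenomicRegion("chr1", 500, 500, name="point"),   # zero-length at the seam
            GenomicRegion("chr1", 100, 500, name="outer"),   # duplicate incl. name
        ]
    )
    return spiked


def neighbor_pairs(results):
    """Flatten engine NeighborResults to oracle-comparable tuples."""
    out = []
    for nb in results:
        out.append(
            (
                (nb.left.region, nb.left.distance) if nb.left else None,
                (nb.right.region, nb.right.distance) if nb.right else None,
            )
        )
    return out


@pytest.fixture
def tmp_text(tmp_path):
    """Write text to a temp file and return its path."""

    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content)
        return str(p)

    return _write
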