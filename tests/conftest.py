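"""Shared fixtures: tiny deterministic catalogs and fragment sets.

The `oracle_*` helpers are deliberately naive per-base recounts, kept
independent of the library's vectorized implementations so they can serve
as ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pausekit.annotation import GeneCatalog, GeneRecord
from pausekit.coverage import CoverageTrack, FragmentSet, pileup


@pytest.fixture
def five_gene_catalog() -> GeneCatalog:
    """Lengths 2k/5k/50k/120k/50k; the two 50-kb genes are 10 kb apart."""
    return GeneCatalog(
        [
            GeneRecord("g1_2k", "chr1", 10_000, 12_000, "+"),
            GeneRecord("g2_5k", "chr1", 100_000, 105_000, "-"),
            GeneRecord("g3_50k", "chr1", 200_000, 250_000, "+"),
            GeneRecord("g4_120k", "chr1", 500_000, 620_000, "+"),
            GeneRecord("g5_50k", "chr1", 260_000, 310_000, "-"),
        ]
    )


@pytest.fixture
def small_track() -> tuple[CoverageTrack, dict]:
    """Seven fragments on a 2-kb chromosome, raw pileup."""
    intervals = pd.DataFrame(
        {
            "chrom": ["chr1"] * 7,
            "start": [10, 10, 50, 100, 700, 990, 1500],
            "end": [20, 20, 160, 180, 900, 1010, 1700],
        }
    )
    frags = FragmentSet(intervals, mapped_count=7)
    sizes = {"chr1": 2000}
    return pileup(frags, sizes), sizes


def oracle_depth(intervals: pd.DataFrame, chrom: str, size: int) -> np.ndarray:
    """Per-base membership count, the slow way."""
    depth = np.zeros(size)
    for row in intervals.itertuples(index=False):
        if row.chrom != chrom:
            continue
        for x in range(row.start, row.end):
            depth[x] += 1
    return depth


def oracle_window_density(
    depth: np.ndarray, gene: GeneRecord, from_off: int, to_off: int
) -> float:
    """Mean depth over a TSS-oriented window, enumerating oriented offsets."""
    vals = []
    for off in range(from_off, to_off):
        pos = gene.tss + off if gene.strand == "+" else gene.tss - off
        if 0 <= pos < len(depth):
            vals.append(depth[pos])
    return float(np.mean(vals))


@pytest.fixture(scope="session")
def fixture_cohort():
    """~20 genes, ~1000 fragments, deterministic; used for oracle equivalence."""
    rng = np.random.default_rng(42)
    records = []
    pos = 8000
    for i in range(20):
        length = int(rng.integers(4000, 9000))
        strand = "+" if i % 2 == 0 else "-"
        records.append(GeneRecord(f"F{i:02d}", "chrF", pos, pos + length, strand))
        pos += length + 8000
    catalog = GeneCatalog(records)
    sizes = {"chrF": pos}
    n_frag = 1000
    starts = rng.integers(0, pos - 300, size=n_frag)
    lengths = rng.integers(100, 300, size=n_frag)
    intervals = pd.DataFrame(
        {"chrom": "chrF", "start": starts, "end": starts + lengths}
    ).sort_values(["start", "end"], ignore_index=True)
    frags = FragmentSet(intervals, mapped_count=n_frag)
    return catalog, frags, sizes
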