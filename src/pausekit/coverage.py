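"""Fragment pileup, depth normalization, input subtraction and window densities.

The signal unit is full-fragment per-base depth: a fragment ``[s, e)``
contributes 1 to every base it covers. Tracks move through three states —
``raw`` counts, ``per10M`` (fragments-per-base per 10 million mapped
fragments), and ``input_subtracted`` (background-corrected, clipped at 0) —
and refuse transitions out of order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import GeneRecord

log = logging.getLogger(__name__)

__all__ = [
    "FragmentSet",
    "CoverageTrack",
    "pileup",
    "normalize_per_10M",
    "subtract_input",
    "window_density",
    "read_fragments_bed",
    "read_chrom_sizes",
    "read_bedgraph",
]

STATES = ("raw", "per10M", "input_subtracted")


@dataclass
class FragmentSet:
    """Deduplicated sequenced fragments as 0-based half-open intervals."""

    intervals: pd.DataFrame  # columns chrom, start, end
    mapped_count: int

    def __post_init__(self) -> None:
        iv = self.intervals
        if not {"chrom", "start", "end"}.issubset(iv.columns):
            raise ValueError("intervals require columns chrom, start, end")
        if (iv["end"] <= iv["start"]).any():
            bad = iv[iv["end"] <= iv["start"]].iloc[0]
            raise ValueError(f"fragment with end <= start: {bad.chrom}:{bad.start}-{bad.end}")
        if self.mapped_count < len(iv):
            raise ValueError("mapped_count smaller than number of fragments")

    def __len__(self) -> int:
        return len(self.intervals)

    def write_bed(self, path: str | Path) -> None:
        self.intervals[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class CoverageTrack:
    """Per-chromosome dense depth vectors with an explicit normalization state."""

    data: dict[str, np.ndarray]
    state: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def copy(self) -> "CoverageTrack":
        return CoverageTrack(
            {c: v.copy() for c, v in self.data.items()}, state=self.state, meta=dict(self.meta)
        )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def scale(self, factor: float) -> "CoverageTrack":
        return CoverageTrack(
            {c: v * factor for c, v in self.data.items()}, state=self.state, meta=dict(self.meta)
        )

    def write_bedgraph(self, path: str | Path) -> None:
        """Write as 4-column bedGraph, run-length collapsing equal values."""
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                v = self.data[chrom]
                if len(v) == 0:
                    continue
                # boundaries where value changes
                change = np.flatnonzero(np.diff(v) != 0) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(v)]))
                for s, e in zip(starts, ends):
                    val = v[s]
                    if val != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{val:.6g}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def read_fragments_bed(path: str | Path, mapped_count: int | None = None) -> FragmentSet:
    """Read a BED3+ fragment file; mapped_count defaults to the row count."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return FragmentSet(df, mapped_count=mapped_count if mapped_count is not None else len(df))


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int], state: str = "raw") -> CoverageTrack:
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for row in df.itertuples(index=False):
        if row.chrom not in data:
            raise KeyError(f"bedGraph chromosome {row.chrom!r} not in chrom sizes")
        data[row.chrom][int(row.start):int(row.end)] = row.value
    return CoverageTrack(data, state=state)


def pileup(fragments: FragmentSet, chrom_sizes: Mapping[str, int]) -> CoverageTrack:
    """Accumulate fragments into per-base raw depth.

    depth(x) = number of fragments whose interval covers base x.
    """
    data = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    for chrom, grp in fragments.intervals.groupby("chrom", sort=False):
        if chrom not in data:
            raise KeyError(f"fragment chromosome {chrom!r} not in chrom sizes")
        n = chrom_sizes[chrom]
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts < 0).any() or (ends > n).any():
            i = int(np.argmax((starts < 0) | (ends > n)))
            raise ValueError(
                f"fragment outside chromosome bounds: {chrom}:{starts[i]}-{ends[i]} (size {n})"
            )
        diff = np.zeros(n + 1, dtype=float)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, ends, -1.0)
        data[chrom] = np.cumsum(diff[:-1])
    return CoverageTrack(data, state="raw", meta={"n_fragments": len(fragments)})


def normalize_per_10M(track: CoverageTrack, mapped_count: int) -> CoverageTrack:
    """Scale raw depth to fragments-per-base per 10 million mapped fragments."""
    if track.state != "raw":
        raise ValueError(f"normalize_per_10M requires a raw track, got {track.state!r}")
    if mapped_count <= 0:
        raise ValueError("mapped_count must be positive")
    factor = 1e7 / mapped_count
    out = track.scale(factor)
    out.state = "per10M"
    out.meta["mapped_count"] = mapped_count
    return out


def subtract_input(sample: CoverageTrack, input_track: CoverageTrack) -> CoverageTrack:
    """Background-correct a sample track; negative values are converted to 0."""
    if sample.state != "per10M" or input_track.state != "per10M":
        raise ValueError("both tracks must be per10M before input subtraction")
    if sample.chrom_sizes != input_track.chrom_sizes:
        raise ValueError("chromosome extents differ between sample and input")
    data = {
        c: np.maximum(sample.data[c] - input_track.data[c], 0.0) for c in sample.data
    }
    return CoverageTrack(data, state="input_subtracted", meta=dict(sample.meta))


def oriented_window(gene: GeneRecord, from_off: int, to_off: int) -> tuple[int, int]:
    """Genomic half-open span of a strand-oriented TSS offset window."""
    if from_off >= to_off:
        raise ValueError("window must satisfy from_off < to_off")
    if gene.strand == "+":
        return gene.tss + from_off, gene.tss + to_off
    return gene.tss - to_off + 1, gene.tss - from_off + 1


def window_density(
    track: CoverageTrack, gene: GeneRecord, from_off: int, to_off: int
) -> float:
    """Mean per-base value over a strand-oriented window around the TSS.

    Offsets are in transcribed orientation: offset 0 is the TSS base and
    positive offsets run into the gene body regardless of strand. Windows
    partially outside the chromosome are clipped (the divisor is the clipped
    width) with a logged warning; a fully out-of-bounds window is an error.
    """
    values = oriented_values(track, gene, from_off, to_off)
    return float(values.mean())


def oriented_values(
    track: CoverageTrack, gene: GeneRecord, from_off: int, to_off: int
) -> np.ndarray:
    """Per-base values for a strand-oriented window, 5'→3' along the gene.

    Bases clipped off the chromosome are dropped (not zero-filled).
    """
    if gene.chrom not in track.data:
        raise KeyError(f"track missing chromosome {gene.chrom!r}")
    g_lo, g_hi = oriented_window(gene, from_off, to_off)
    n = len(track.data[gene.chrom])
    c_lo, c_hi = max(g_lo, 0), min(g_hi, n)
    if c_lo >= c_hi:
        raise ValueError(
            f"window ({from_off},{to_off}) of gene {gene.gene_id} lies entirely "
            f"outside chromosome {gene.chrom}"
        )
    if (c_lo, c_hi) != (g_lo, g_hi):
        log.warning(
            "window (%d,%d) of gene %s clipped to chromosome bounds", from_off, to_off, gene.gene_id
        )
    vals = track.data[gene.chrom][c_lo:c_hi]
    if gene.strand == "-":
        vals = vals[::-1]
    return vals
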