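"""Gene catalogs and the selection filters applied before profiling.

All coordinates are 0-based half-open (BED convention). The TSS of a
minus-strand gene is ``end - 1``; its TTS is ``start``. Selection filters
return new catalogs and record their parameters in ``provenance`` so a
written catalog can state how it was derived.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GeneRecord",
    "GeneCatalog",
    "load_tss_table",
    "select_nonoverlapping",
    "select_expressed_by_length",
    "rank_top_bound",
]


@dataclass(frozen=True)
class GeneRecord:
    """One oriented gene interval.

    Attributes
    ----------
    gene_id : str
        Unique identifier.
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open genomic span; ``end > start``.
    strand : str
        ``"+"`` or ``"-"``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneCatalog:
    """Ordered collection of genes plus the filter parameters that produced it."""

    records: list[GeneRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene_id(s): {', '.join(dupes[:5])}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __getitem__(self, key: int) -> GeneRecord:
        return self.records[key]

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def get(self, gene_id: str) -> GeneRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.records],
                "start": [r.start for r in self.records],
                "end": [r.end for r in self.records],
                "gene_id": [r.gene_id for r in self.records],
                "strand": [r.strand for r in self.records],
            }
        )

    def write_bed6(self, path: str | Path, sidecar: bool = True) -> None:
        """Write the catalog as BED6 plus a JSON provenance sidecar."""
        df = self.to_frame()
        df["score"] = 0
        df[["chrom", "start", "end", "gene_id", "score", "strand"]].to_csv(
            path, sep="\t", header=False, index=False
        )
        if sidecar:
            with open(str(path) + ".provenance.json", "w") as fh:
                json.dump(self.provenance, fh, indent=2, sort_keys=True)


def _record_from_row(row: Mapping, lineno: int) -> GeneRecord:
    strand = str(row["strand"])
    if strand not in ("+", "-"):
        raise ValueError(f"line {lineno}: unknown strand {strand!r} (expected '+' or '-')")
    try:
        start = int(row["start"])
        end = int(row["end"])
    except (TypeError, ValueError) as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    return GeneRecord(
        gene_id=str(row["gene_id"]), chrom=str(row["chrom"]), start=start, end=end, strand=strand
    )


def load_tss_table(path: str | Path, format: str = "BED6") -> GeneCatalog:
    """Load a gene/TSS table as a :class:`GeneCatalog`.

    Parameters
    ----------
    path :
        BED6 file (chrom, start, end, name, score, strand; no header) or a
        TSV with header columns chrom/start/end/strand/gene_id.
    format :
        ``"BED6"`` or ``"TSS-TSV"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "BED6":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            dtype=str,
        )
        if df.shape[1] != 6:
            raise ValueError(f"{path}: BED6 requires 6 columns, found {df.shape[1]}")
        df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
    elif format == "TSS-TSV":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"chrom", "start", "end", "strand", "gene_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    else:
        raise ValueError(f"unknown format {format!r}")

    records = []
    offset = 1 if format == "BED6" else 2  # header line counts for TSV
    for i, row in enumerate(df.to_dict("records")):
        records.append(_record_from_row(row, lineno=i + offset))
    return GeneCatalog(records, provenance={"source": str(path), "format": format})


def select_nonoverlapping(
    catalog: GeneCatalog,
    min_len: int = 3000,
    max_len: int | None = 100_000,
    flank: int = 2000,
) -> GeneCatalog:
    """Length filter plus isolation filter.

    Keeps genes with ``min_len <= length <= max_len`` whose span expanded by
    ``flank`` on both sides intersects no *other* gene in the input catalog
    (the isolation test runs against the full input, so a short neighbour
    still disqualifies a gene). The defaults reproduce the 3–100 kb,
    2-kb-spacing selection used for promoter-proximal profiling.
    """
    if min_len < 0 or flank < 0:
        raise ValueError("min_len and flank must be non-negative")
    kept: list[GeneRecord] = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for r in catalog:
        by_chrom.setdefault(r.chrom, []).append(r)

    for r in catalog:
        if r.length < min_len:
            continue
        if max_len is not None and r.length > max_len:
            continue
        lo, hi = r.start - flank, r.end + flank
        isolated = True
        for other in by_chrom[r.chrom]:
            if other.gene_id == r.gene_id:
                continue
            if other.start < hi and lo < other.end:
                isolated = False
                break
        if isolated:
            kept.append(r)
    prov = dict(catalog.provenance)
    prov["select_nonoverlapping"] = {
        "min_len": min_len,
        "max_len": max_len,
        "flank": flank,
        "bounds": "inclusive",
        "n_in": len(catalog),
        "n_out": len(kept),
    }
    return GeneCatalog(kept, provenance=prov)


def select_expressed_by_length(
    catalog: GeneCatalog,
    rpkm: Mapping[str, float],
    min_rpkm: float = 0.05,
    tss_spacing: int = 10_000,
    length_bounds: tuple[int, int] = (25_000, 50_000),
) -> GeneCatalog:
    """Expression, length-class and TSS-spacing filter for nascent-RNA profiling.

    A gene is retained if its expression is at least ``min_rpkm``, its length
    lies in ``(lo, hi]`` and its TSS is at least ``tss_spacing`` away from the
    TSS of every other gene in the catalog. Genes absent from ``rpkm`` count
    as unexpressed (0).
    """
    for g, v in rpkm.items():
        if v < 0:
            raise ValueError(f"negative RPKM for {g}: {v}")
    lo, hi = length_bounds
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for r in catalog:
        tss_by_chrom.setdefault(r.chrom, []).append((r.tss, r.gene_id))

    kept = []
    for r in catalog:
        if rpkm.get(r.gene_id, 0.0) < min_rpkm:
            continue
        if not (lo < r.length <= hi):
            continue
        crowded = any(
            gid != r.gene_id and abs(t - r.tss) < tss_spacing for t, gid in tss_by_chrom[r.chrom]
        )
        if crowded:
            continue
        kept.append(r)
    prov = dict(catalog.provenance)
    prov["select_expressed_by_length"] = {
        "min_rpkm": min_rpkm,
        "tss_spacing": tss_spacing,
        "length_bounds": [lo, hi],
        "n_in": len(catalog),
        "n_out": len(kept),
    }
    return GeneCatalog(kept, provenance=prov)


def rank_top_bound(
    catalog: GeneCatalog,
    track,
    window: tuple[int, int] = (-1000, 1000),
    n: int = 3000,
) -> GeneCatalog:
    """Top-``n`` genes by mean signal density in a strand-oriented TSS window.

    Used to pick the most strongly factor-bound genes (e.g. top 3000 by
    promoter signal in unirradiated cells). Ties broken by gene_id so the
    ranking is deterministic. The ranking window and per-gene densities are
    recorded in provenance.
    """
    from .coverage import window_density

    if n > len(catalog):
        raise ValueError(f"n={n} exceeds catalog size {len(catalog)}")
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy from_off < to_off")
    for r in catalog:
        if r.chrom not in track.chrom_sizes:
            raise KeyError(f"track missing chromosome {r.chrom!r}")
    dens = np.array([window_density(track, r, lo, hi) for r in catalog])
    ids = np.array(catalog.gene_ids)
    order = np.lexsort((ids, -dens))  # density desc, gene_id asc on ties
    top = order[:n]
    kept = [catalog.records[i] for i in top]
    prov = dict(catalog.provenance)
    prov["rank_top_bound"] = {
        "window": [lo, hi],
        "n": n,
        "ranking": [
            {"gene_id": str(ids[i]), "density": float(dens[i])} for i in top
        ],
    }
    return GeneCatalog(kept, provenance=prov)
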