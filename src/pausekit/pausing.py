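"""Traveling ratios and UV-shift classification.

The traveling ratio (pausing index) of a gene is the signal density in the
early gene body divided by the density in the promoter-proximal window; a
larger value means more polymerase released from the pause site into
productive elongation. Ratios are normalized so the unirradiated (mock)
cohort averages 1, and a gene "shifts" in a UV/mock comparison when its
UV ratio exceeds its mock ratio. Genes shifting in *every* comparison are
classed ALL_SHIFT, the rest MIXED_SHIFT; genes with an empty promoter
window have an infinite ratio and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneCatalog, GeneRecord
from .coverage import CoverageTrack, oriented_values

__all__ = [
    "TRWindows",
    "RNAPII_WINDOWS",
    "PAF1_WINDOWS",
    "traveling_ratio",
    "traveling_ratio_table",
    "normalize_tr",
    "fraction_above_one",
    "classify_shift",
]


@dataclass(frozen=True)
class TRWindows:
    """Promoter-proximal and gene-body offset windows, TSS-oriented."""

    promoter: tuple[int, int]
    body: tuple[int, int]
    label: str = "custom"

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("promoter", self.promoter), ("body", self.body)):
            if lo >= hi:
                raise ValueError(f"{name} window is degenerate: ({lo}, {hi})")


#: RNAPII preset: body (+250, +3000) over promoter (−750, +250)
RNAPII_WINDOWS = TRWindows(promoter=(-750, 250), body=(250, 3000), label="RNAPII")
#: PAF1 preset: body (TSS, +1000) over promoter (−750, TSS)
PAF1_WINDOWS = TRWindows(promoter=(-750, 0), body=(0, 1000), label="PAF1")


def _window_quantity(
    track: CoverageTrack, gene: GeneRecord, window: tuple[int, int], convention: str
) -> float:
    vals = oriented_values(track, gene, window[0], window[1])
    return float(vals.mean()) if convention == "density" else float(vals.sum())


def traveling_ratio(
    track: CoverageTrack,
    gene: GeneRecord,
    windows: TRWindows = RNAPII_WINDOWS,
    convention: str = "density",
) -> tuple[float, float, float]:
    """Per-gene (promoter, body, ratio) for one track.

    ``convention`` selects per-bp densities (default; a flat track then gives
    ratio 1) or raw window sums; after cohort normalization the two agree
    because the window-length factor is constant across genes. A promoter
    quantity of 0 yields ratio NaN (non-finite, excluded downstream).
    """
    if convention not in ("density", "sum"):
        raise ValueError(f"convention must be 'density' or 'sum', got {convention!r}")
    prom = _window_quantity(track, gene, windows.promoter, convention)
    body = _window_quantity(track, gene, windows.body, convention)
    tr = body / prom if prom > 0 else float("nan")
    return prom, body, tr


def traveling_ratio_table(
    tracks: Mapping[str, CoverageTrack],
    catalog: GeneCatalog,
    windows: TRWindows = RNAPII_WINDOWS,
    convention: str = "density",
) -> pd.DataFrame:
    """Long-format table of per-gene, per-sample traveling ratios.

    Columns: gene_id, sample, promoter_density, body_density, tr, finite.
    """
    rows = []
    for sample, track in tracks.items():
        for gene in catalog:
            prom, body, tr = traveling_ratio(track, gene, windows, convention)
            rows.append((gene.gene_id, sample, prom, body, tr, np.isfinite(tr)))
    return pd.DataFrame(
        rows, columns=["gene_id", "sample", "promoter_density", "body_density", "tr", "finite"]
    )


def normalize_tr(table: pd.DataFrame, mock_samples: Sequence[str]) -> pd.DataFrame:
    """Divide every ratio by the mean finite mock ratio (mock average set to 1)."""
    mock = table[table["sample"].isin(mock_samples) & table["finite"]]
    if mock.empty:
        raise ValueError("no finite traveling ratio in any mock sample")
    denom = mock["tr"].mean()
    out = table.copy()
    out["normalized_tr"] = out["tr"] / denom
    out.attrs["mock_mean_tr"] = float(denom)
    out.attrs["mock_samples"] = list(mock_samples)
    return out


def fraction_above_one(table: pd.DataFrame, sample: str) -> tuple[float, int, int]:
    """(fraction, n_above, n_finite) of genes with normalized ratio strictly > 1."""
    if "normalized_tr" not in table.columns:
        raise ValueError("normalize_tr must be applied first")
    sub = table[(table["sample"] == sample) & table["finite"]]
    n_finite = len(sub)
    n_above = int((sub["normalized_tr"] > 1).sum())
    frac = n_above / n_finite if n_finite else float("nan")
    return frac, n_above, n_finite


def classify_shift(
    table: pd.DataFrame,
    comparisons: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Classify genes by replicate-consistency of the UV-induced ratio increase.

    Each comparison is a (uv_sample, mock_reference_sample) pair; its boolean
    is ``tr_uv / tr_mock > 1``. ALL_SHIFT requires the increase in every
    comparison; otherwise MIXED_SHIFT. A gene is classifiable only when all
    involved ratios are finite; others are reported with class UNCLASSIFIED.

    Returns a frame with gene_id, one ``shift_<uv>_vs_<mock>`` boolean column
    per comparison, n_shifting, and class.
    """
    if not comparisons:
        raise ValueError("at least one (uv, mock) comparison is required")
    tr = table.pivot(index="gene_id", columns="sample", values="tr")
    for uv, mock in comparisons:
        for s in (uv, mock):
            if s not in tr.columns:
                raise KeyError(f"sample {s!r} absent from table")
    out = pd.DataFrame(index=tr.index)
    finite = pd.Series(True, index=tr.index)
    for uv, mock in comparisons:
        ratio = tr[uv] / tr[mock]
        out[f"shift_{uv}_vs_{mock}"] = ratio > 1
        finite &= np.isfinite(tr[uv]) & np.isfinite(tr[mock]) & (tr[mock] > 0)
    bool_cols = [c for c in out.columns if c.startswith("shift_")]
    out["n_shifting"] = out[bool_cols].sum(axis=1)
    out["class"] = np.where(out["n_shifting"] == len(comparisons), "ALL_SHIFT", "MIXED_SHIFT")
    out.loc[~finite, "class"] = "UNCLASSIFIED"
    return out.reset_index()
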