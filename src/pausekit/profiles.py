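"""Anchored per-gene profiles, averaged metaprofiles and redistribution curves.

A metaprofile is the per-bin mean (or median) of many strand-oriented
per-gene profiles around a common anchor (TSS or TTS). AUC normalization
divides the averaged profile by its integral so that conditions with
different overall read density can be compared shape-to-shape; the
redistribution curve is then the +UV minus mock difference of two AUC
profiles and integrates to zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneRecord
from .coverage import CoverageTrack, window_density

__all__ = [
    "AnchoredProfile",
    "MetaProfile",
    "anchored_profile",
    "meta_profile",
    "redistribution",
    "metagene_scaled",
]

AUC_TOL = 1e-9


@dataclass
class AnchoredProfile:
    """Binned strand-oriented signal for one gene around an anchor."""

    gene_id: str
    anchor: str  # "TSS" or "TTS"
    bins: np.ndarray
    bin_size: int
    span: tuple[int, int]

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)
        lo, hi = self.span
        expected = (hi - lo) // self.bin_size if self.bin_size > 0 else len(self.bins)
        if self.bin_size > 0 and len(self.bins) != expected:
            raise ValueError(
                f"{self.gene_id}: {len(self.bins)} bins but span/bin_size gives {expected}"
            )

    @property
    def offsets(self) -> np.ndarray:
        """Bin start offsets relative to the anchor."""
        lo = self.span[0]
        return lo + self.bin_size * np.arange(len(self.bins))


@dataclass
class MetaProfile:
    """Averaged occupancy across a gene set."""

    bins: np.ndarray
    n_genes: int
    bin_size: int
    span: tuple[int, int]
    anchor: str = "TSS"
    normalization: str = "none"  # none | AUC | global-scaled
    label: str = ""

    def __post_init__(self) -> None:
        self.bins = np.asarray(self.bins, dtype=float)

    @property
    def offsets(self) -> np.ndarray:
        return self.span[0] + self.bin_size * np.arange(len(self.bins))

    def integral(self) -> float:
        return float(np.sum(self.bins) * self.bin_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "value": self.bins})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def anchored_profile(
    track: CoverageTrack,
    gene: GeneRecord,
    anchor: str = "TSS",
    span: tuple[int, int] = (-2000, 5000),
    bin_size: int = 50,
) -> AnchoredProfile:
    """Bin strand-oriented density around the TSS or TTS of one gene."""
    lo, hi = span
    if (hi - lo) % bin_size:
        raise ValueError("span must be a multiple of bin_size")
    if anchor not in ("TSS", "TTS"):
        raise ValueError(f"anchor must be TSS or TTS, got {anchor!r}")
    shift = 0 if anchor == "TSS" else _tts_offset(gene)
    n_bins = (hi - lo) // bin_size
    bins = np.empty(n_bins)
    for b in range(n_bins):
        f = lo + b * bin_size + shift
        bins[b] = window_density(track, gene, f, f + bin_size)
    return AnchoredProfile(gene.gene_id, anchor, bins, bin_size, span)


def _tts_offset(gene: GeneRecord) -> int:
    # TTS expressed as an offset from the TSS in transcribed orientation
    return gene.length - 1


def meta_profile(
    profiles: Sequence[AnchoredProfile],
    stat: str = "mean",
    normalize: str = "none",
    label: str = "",
) -> MetaProfile:
    """Per-bin mean or median across genes, optionally AUC-normalized."""
    if not profiles:
        raise ValueError("meta_profile requires at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if (p.anchor, p.span, p.bin_size) != (first.anchor, first.span, first.bin_size):
            raise ValueError("profiles mix anchors, spans or bin sizes")
    mat = np.vstack([p.bins for p in profiles])
    if stat == "mean":
        bins = mat.mean(axis=0)
    elif stat == "median":
        bins = np.median(mat, axis=0)
    else:
        raise ValueError(f"stat must be mean or median, got {stat!r}")
    norm = "none"
    if normalize == "AUC":
        area = float(np.sum(bins) * first.bin_size)
        if area <= 0:
            raise ValueError("cannot AUC-normalize a profile with non-positive integral")
        bins = bins / area
        norm = "AUC"
    elif normalize != "none":
        raise ValueError(f"normalize must be none or AUC, got {normalize!r}")
    return MetaProfile(
        bins, n_genes=len(profiles), bin_size=first.bin_size, span=first.span,
        anchor=first.anchor, normalization=norm, label=label,
    )


def redistribution(uv: MetaProfile, mock: MetaProfile) -> MetaProfile:
    """Signed per-bin UV minus mock difference profile.

    With AUC-normalized inputs the difference integrates to 0: signal lost at
    the pause position reappears downstream, making the repositioning visible
    as a negative lobe at the anchor and a positive lobe in the early body.
    """
    if (uv.span, uv.bin_size, uv.anchor) != (mock.span, mock.bin_size, mock.anchor):
        raise ValueError("profiles are not on a common grid")
    if uv.normalization != mock.normalization:
        raise ValueError(
            f"normalization mismatch: {uv.normalization!r} vs {mock.normalization!r}"
        )
    return MetaProfile(
        uv.bins - mock.bins,
        n_genes=uv.n_genes,
        bin_size=uv.bin_size,
        span=uv.span,
        anchor=uv.anchor,
        normalization=uv.normalization,
        label=f"{uv.label}-{mock.label}" if uv.label or mock.label else "redistribution",
    )


def metagene_scaled(
    track: CoverageTrack,
    gene: GeneRecord,
    flank: int = 2000,
    body_bins: int = 100,
    flank_bin_size: int = 50,
) -> AnchoredProfile:
    """Length-normalized gene-body profile with fixed-width flanks.

    The body is divided into ``body_bins`` equal genomic fractions; each body
    bin is the exact mean density over its (possibly fractional) span,
    computed from the cumulative coverage so partial bases are weighted by
    their overlap. Flanks upstream of the TSS and downstream of the TTS are
    binned at ``flank_bin_size``.
    """
    if gene.length < body_bins:
        raise ValueError(f"gene {gene.gene_id} shorter than body_bins")
    if flank % flank_bin_size:
        raise ValueError("flank must be a multiple of flank_bin_size")

    # oriented per-base vector covering [-flank, length + flank)
    from .coverage import oriented_values

    vals = oriented_values(track, gene, -flank, gene.length + flank)
    if len(vals) != gene.length + 2 * flank:
        raise ValueError(f"gene {gene.gene_id}: flank extends beyond chromosome")

    n_flank_bins = flank // flank_bin_size
    up = vals[: flank].reshape(n_flank_bins, flank_bin_size).mean(axis=1)
    down = vals[flank + gene.length :].reshape(n_flank_bins, flank_bin_size).mean(axis=1)

    body = vals[flank : flank + gene.length]
    cum = np.concatenate(([0.0], np.cumsum(body)))

    def integral(t: float) -> float:
        i = int(np.floor(t))
        if i >= gene.length:
            return float(cum[-1])
        return float(cum[i] + (t - i) * body[i])

    edges = np.linspace(0, gene.length, body_bins + 1)
    body_vals = np.array(
        [
            (integral(edges[b + 1]) - integral(edges[b])) / (edges[b + 1] - edges[b])
            for b in range(body_bins)
        ]
    )
    bins = np.concatenate([up, body_vals, down])
    # scaled coordinates: one unit per bin so genes of different lengths share a grid
    return AnchoredProfile(gene.gene_id, "TSS", bins, bin_size=1, span=(0, len(bins)))
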