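"""Gene-body profiling of histone H2B monoubiquitylation (Ub-H2B).

Ub-H2B is deposited co-transcriptionally and tracks elongation, so its
gene-body profile reads out how far polymerases travel after UV. Profiles
are background-subtracted against a point just upstream of the TSS and then
rescaled so each condition's integral equals the global Ub-H2B level
measured independently by immunofluorescence (reference condition = 1);
without that rescaling a ChIP profile only reports shape, not amount.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import MetaProfile

__all__ = ["GlobalLevel", "read_global_levels", "baseline_subtract_upstream", "scale_to_global"]


@dataclass(frozen=True)
class GlobalLevel:
    """Imaging-derived global mark level relative to a reference condition."""

    condition: str
    fraction: float

    def __post_init__(self) -> None:
        if self.fraction < 0:
            raise ValueError(f"fraction must be non-negative, got {self.fraction}")


def read_global_levels(path: str | Path) -> dict[str, GlobalLevel]:
    """Read a condition→fraction TSV (columns: condition, fraction)."""
    df = pd.read_csv(path, sep="\t")
    if not {"condition", "fraction"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns condition, fraction")
    return {
        str(r.condition): GlobalLevel(str(r.condition), float(r.fraction))
        for r in df.itertuples(index=False)
    }


def baseline_subtract_upstream(profile: MetaProfile, baseline_offset: int = 200) -> MetaProfile:
    """Subtract the bin at ``baseline_offset`` bp upstream of the TSS; clip at 0."""
    target = -baseline_offset
    offsets = profile.offsets
    idx = np.flatnonzero((offsets <= target) & (target < offsets + profile.bin_size))
    if idx.size == 0:
        raise ValueError(
            f"baseline position {target} bp outside profile span {profile.span}"
        )
    baseline = profile.bins[idx[0]]
    return MetaProfile(
        np.maximum(profile.bins - baseline, 0.0),
        n_genes=profile.n_genes,
        bin_size=profile.bin_size,
        span=profile.span,
        anchor=profile.anchor,
        normalization=profile.normalization,
        label=profile.label,
    )


def scale_to_global(profile: MetaProfile, level: GlobalLevel) -> MetaProfile:
    """Rescale so the profile integral equals the imaging-derived fraction."""
    area = profile.integral()
    if area <= 0:
        raise ValueError("cannot scale a profile with non-positive integral")
    return MetaProfile(
        profile.bins * (level.fraction / area),
        n_genes=profile.n_genes,
        bin_size=profile.bin_size,
        span=profile.span,
        anchor=profile.anchor,
        normalization="global-scaled",
        label=level.condition or profile.label,
    )
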