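"""Synthetic cohorts with the pausing / release / elongation structure.

The generator lays non-overlapping genes on one synthetic chromosome and
draws sequencing fragments from an occupancy intensity built from the
features the downstream analysis quantifies:

* a Gaussian promoter-proximal pause peak at the TSS,
* a flat gene-body level attenuated as ``exp(-x/L)`` when UV lesions with
  mean spacing ``L`` block elongation (1 CPD per 16 kb at ~7 J/m² scales
  inversely with dose),
* a Gaussian peak downstream of the TTS,
* uniform background.

UV-induced pause release moves a fraction ``f`` of the pause mass into an
exponentially decaying zone over the first 1–2 kb of the body — the
repositioning signature. CSB-KO forbids release and adds global signal
loss; PAF1 depletion forbids release. Fragment counts are Poisson so
replicates carry realistic shot noise, and every draw is
generator-seeded: identical specs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneCatalog, GeneRecord
from .coverage import CoverageTrack, FragmentSet
from .bruseq import NascentLevel

__all__ = [
    "OccupancyModel",
    "ConditionSpec",
    "SimSpec",
    "simulate_catalog",
    "expected_intensity",
    "simulate_chip_library",
    "simulate_bru_track",
    "simulate_intensity_matrix",
    "write_protein_groups_tsv",
]

CHROM = "chrSim"

#: Lesion spacing anchor: ~1 CPD per 16 kb of template at a 7 J/m²-equivalent
#: dose; spacing scales inversely with dose.
CPD_SPACING_7J = 16_000.0


def damage_spacing_for_dose(dose_jm2: float) -> float:
    """Mean lesion spacing (bp) for a UV dose, anchored at 16 kb per 7 J/m²."""
    if dose_jm2 <= 0:
        return float("inf")
    return CPD_SPACING_7J * 7.0 / dose_jm2


@dataclass(frozen=True)
class OccupancyModel:
    """Relative occupancy intensity parameters (expected fragments/bp scale)."""

    pause_height: float = 20.0
    pause_width: float = 150.0
    body_level: float = 1.0
    tts_height: float = 5.0
    tts_width: float = 500.0
    background: float = 0.05

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


NO_RELEASE_GENOTYPES = ("CSB_KO", "PAF1_depleted")


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition of the simulated study."""

    label: str
    release_fraction: float = 0.0
    release_zone: int = 2000
    damage_spacing: float = float("inf")  # bp; inf = undamaged
    global_scale: float = 1.0
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if not (0.0 <= self.release_fraction <= 1.0):
            raise ValueError("release_fraction must lie in [0, 1]")
        if self.genotype not in ("WT", "CSB_KO", "PAF1_depleted"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.genotype in NO_RELEASE_GENOTYPES and self.release_fraction > 0:
            raise ValueError(f"{self.genotype} cannot release paused polymerase")


MOCK = ConditionSpec(label="mock")


@dataclass
class SimSpec:
    """Reproducible description of a simulated study."""

    n_genes: int = 50
    length_range: tuple[int, int] = (3000, 100_000)
    spacing: int = 6000
    seed: int = 0
    samples: list[dict] = field(default_factory=list)  # label/condition/depth/seed

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "n_genes": self.n_genes,
                    "length_range": list(self.length_range),
                    "spacing": self.spacing,
                    "seed": self.seed,
                    "samples": self.samples,
                },
                fh,
                sort_keys=True,
            )


def simulate_catalog(
    n_genes: int,
    length_range: tuple[int, int] = (3000, 100_000),
    spacing: int = 6000,
    seed: int = 0,
) -> tuple[GeneCatalog, dict[str, int]]:
    """Lay non-overlapping genes with alternating strands on one chromosome.

    Lengths are drawn log-uniformly over ``length_range`` (gene lengths are
    roughly log-distributed genome-wide); consecutive genes are separated by
    exactly ``spacing`` bp.
    """
    if spacing < 0:
        raise ValueError("spacing must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes)).astype(int)
    records = []
    pos = spacing
    for i, length in enumerate(lengths):
        strand = "+" if i % 2 == 0 else "-"
        records.append(
            GeneRecord(gene_id=f"G{i:04d}", chrom=CHROM, start=pos, end=pos + int(length), strand=strand)
        )
        pos += int(length) + spacing
    chrom_sizes = {CHROM: pos}
    catalog = GeneCatalog(
        records,
        provenance={
            "simulated": {
                "n_genes": n_genes,
                "length_range": [lo, hi],
                "spacing": spacing,
                "seed": int(seed),
            }
        },
    )
    return catalog, chrom_sizes


def _gene_intensity(
    gene: GeneRecord, model: OccupancyModel, cond: ConditionSpec, released: bool
) -> tuple[np.ndarray, int]:
    """Oriented per-base intensity for one gene (without background/global scale).

    Returns the intensity over offsets [-4*pause_width, length + 4*tts_width)
    and the offset of the array origin relative to the TSS.
    """
    pw, tw = model.pause_width, model.tts_width
    lo = -int(4 * pw)
    hi = gene.length + int(4 * tw)
    x = np.arange(lo, hi, dtype=float)
    lam = np.zeros_like(x)

    f = cond.release_fraction if released else 0.0
    pause = model.pause_height * np.exp(-(x**2) / (2 * pw**2))
    lam += (1.0 - f) * pause

    if f > 0:
        zone = min(cond.release_zone, gene.length)
        # redistribute the full pause mass into an exponential ramp over (0, zone]
        mass = f * pause.sum()
        tau = zone / 3.0
        in_zone = (x > 0) & (x <= zone)
        shape = np.exp(-x[in_zone] / tau)
        lam[in_zone] += mass * shape / shape.sum()

    body = (x > 0) & (x < gene.length)
    L = cond.damage_spacing
    decay = np.exp(-x[body] / L) if np.isfinite(L) else 1.0
    lam[body] += model.body_level * decay

    lam += model.tts_height * np.exp(-((x - gene.length) ** 2) / (2 * tw**2))
    return lam, lo


def expected_intensity(
    catalog: GeneCatalog,
    model: OccupancyModel,
    cond: ConditionSpec,
    chrom_sizes: Mapping[str, int],
    release_mask: Mapping[str, bool] | None = None,
) -> dict[str, np.ndarray]:
    """Per-base expected relative occupancy for a condition.

    ``release_mask`` restricts UV release to a responder subset of genes
    (missing genes default to released when the condition releases at all);
    this is how cohorts with known responder truth labels are built.
    """
    lam = {c: np.full(n, model.background, dtype=float) for c, n in chrom_sizes.items()}
    for gene in catalog:
        released = True if release_mask is None else bool(release_mask.get(gene.gene_id, True))
        g, lo = _gene_intensity(gene, model, cond, released)
        if gene.strand == "+":
            g_start = gene.tss + lo
            seg = g
        else:
            g_start = gene.tss - (lo + len(g)) + 1
            seg = g[::-1]
        arr = lam[gene.chrom]
        s, e = max(g_start, 0), min(g_start + len(seg), len(arr))
        arr[s:e] += seg[s - g_start : e - g_start]
    for arr in lam.values():
        arr *= cond.global_scale
    return lam


def simulate_chip_library(
    catalog: GeneCatalog,
    model: OccupancyModel,
    cond: ConditionSpec,
    depth: int,
    chrom_sizes: Mapping[str, int],
    fragment_len: int = 200,
    seed: int = 0,
    release_mask: Mapping[str, bool] | None = None,
) -> FragmentSet:
    """Draw a Poisson fragment library from the condition's occupancy.

    ``depth`` calibrates the *mock* expected fragment total, so conditions
    with global loss or damage attenuation yield proportionally fewer
    fragments, as a fixed sequencing effort would show after depth
    normalization. Fragments are fixed-length and centered on the sampled
    position.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    lam_cond = expected_intensity(catalog, model, cond, chrom_sizes, release_mask)
    lam_mock = expected_intensity(catalog, model, MOCK, chrom_sizes)
    total_mock = sum(a.sum() for a in lam_mock.values())
    scale = depth / total_mock
    rng = np.random.default_rng(seed)
    frames = []
    half = fragment_len // 2
    for chrom in sorted(lam_cond):
        counts = rng.poisson(scale * lam_cond[chrom])
        centers = np.repeat(np.arange(len(counts)), counts)
        if centers.size == 0:
            continue
        n = chrom_sizes[chrom]
        starts = np.clip(centers - half, 0, n - fragment_len)
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + fragment_len})
        )
    iv = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "start", "end"])
    )
    iv = iv.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    return FragmentSet(iv, mapped_count=len(iv))


def _recovery(x: np.ndarray, cond: ConditionSpec, time_h: float, speed: float) -> np.ndarray:
    """Fractional recovery of nascent transcription at body position x."""
    L = cond.damage_spacing
    if not np.isfinite(L):
        return np.ones_like(x)
    attenuated = np.exp(-x / L)
    if cond.genotype == "PAF1_depleted":
        # pause region keeps initiating, but no wave advances
        front = 500.0
    else:
        front = speed * time_h
    return np.where(x < front, 1.0, attenuated)


def simulate_bru_track(
    catalog: GeneCatalog,
    time_h: float,
    cond: ConditionSpec,
    chrom_sizes: Mapping[str, int],
    elongation_speed: float = 4000.0,
    depth: int = 1_000_000,
    seed: int = 0,
) -> tuple[CoverageTrack, NascentLevel]:
    """Per-base nascent-read-start counts under the recovery-wave model.

    Expected signal is the mock gene-body level times the recovery fraction:
    1 up to the wave front at ``elongation_speed × time_h`` bp, and
    ``exp(-x/L)`` beyond it, where L is the condition's lesion spacing.
    ``depth`` calibrates the mock expected read total. The emitted
    NascentLevel is the genome-wide expected signal fraction relative to
    mock — the quantity 5-EU imaging measures.
    """
    if elongation_speed <= 0:
        raise ValueError("elongation_speed must be positive")
    rng = np.random.default_rng(seed)
    lam = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    mock_total = 0.0
    for gene in catalog:
        x = np.arange(gene.length, dtype=float)
        level = cond.global_scale * _recovery(x, cond, time_h, elongation_speed)
        mock_total += gene.length
        if gene.strand == "+":
            lam[gene.chrom][gene.start : gene.end] += level
        else:
            lam[gene.chrom][gene.start : gene.end] += level[::-1]
    per_base = depth / mock_total
    total_expected = 0.0
    for chrom, arr in lam.items():
        arr *= per_base
        total_expected += arr.sum()
    counts = {c: rng.poisson(a).astype(float) for c, a in lam.items()}
    n_reads = int(sum(a.sum() for a in counts.values()))
    track = CoverageTrack(counts, state="raw", meta={"n_fragments": n_reads})
    fraction = total_expected / depth
    return track, NascentLevel(condition=cond.label, fraction=float(fraction))


def simulate_intensity_matrix(
    n_proteins: int = 1000,
    n_enriched: int = 50,
    effect_log2: float = 2.0,
    group_sizes: tuple[int, int] = (4, 4),
    protein_sd: float = 2.0,
    noise_sd: float = 0.3,
    base_mean: float = 25.0,
    missing_max: float = 0.9,
    missing_midpoint: float = 21.0,
    missing_scale: float = 1.0,
    seed: int = 0,
):
    """Log2 intensity matrix with planted UV enrichment and MNAR missingness.

    Protein baselines are Normal(base_mean, protein_sd); replicate noise is
    Normal(0, noise_sd); the first ``n_enriched`` proteins gain
    ``effect_log2`` in the UV group. Each measured value is censored with
    logistic probability ``missing_max / (1 + exp((x - midpoint)/scale))``,
    so low-intensity values go missing preferentially — the left-censoring
    the down-shifted imputation assumes. Set ``missing_max=0`` for a
    complete matrix.

    Returns (IntensityMatrix in log2 state, truth label Series, GroupDesign).
    """
    from .proteomics import GroupDesign, IntensityMatrix

    if n_enriched > n_proteins:
        raise ValueError("n_enriched cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    n_uv, n_mock = group_sizes
    samples = [f"UV_{i+1}" for i in range(n_uv)] + [f"mock_{i+1}" for i in range(n_mock)]
    design = GroupDesign({s: ("UV" if s.startswith("UV") else "mock") for s in samples})
    base = rng.normal(base_mean, protein_sd, size=n_proteins)
    truth = np.zeros(n_proteins, dtype=bool)
    truth[:n_enriched] = True
    vals = np.empty((n_proteins, len(samples)))
    for j, s in enumerate(samples):
        shift = np.where(truth & (design.groups[s] == "UV"), effect_log2, 0.0)
        vals[:, j] = base + shift + rng.normal(0.0, noise_sd, size=n_proteins)
    if missing_max > 0:
        p_miss = missing_max / (1.0 + np.exp((vals - missing_midpoint) / missing_scale))
        vals[rng.uniform(size=vals.shape) < p_miss] = np.nan
    ids = [f"P{i:05d}" for i in range(n_proteins)]
    values = pd.DataFrame(vals, index=pd.Index(ids, name="Protein IDs"), columns=samples)
    matrix = IntensityMatrix(values=values, flags=None, ibaq=None, state="log2")
    return matrix, pd.Series(truth, index=values.index, name="enriched"), design


def write_protein_groups_tsv(
    matrix, path: str | Path, truth: pd.Series | None = None
) -> None:
    """Export a log2 matrix as a MaxQuant-style linear proteinGroups TSV.

    Missing values become 0, matching MaxQuant output conventions.
    """
    linear = (2.0 ** matrix.values).fillna(0.0)
    df = linear.rename(columns=lambda c: f"LFQ intensity {c}")
    df.insert(0, "Protein IDs", matrix.values.index)
    for col in ("Reverse", "Potential contaminant", "Only identified by site"):
        df[col] = ""
    if truth is not None:
        df["planted_enriched"] = np.where(truth.reindex(matrix.values.index), "+", "")
    df.to_csv(path, sep="\t", index=False)
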