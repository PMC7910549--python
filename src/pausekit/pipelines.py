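"""End-to-end pipelines driven by a YAML run configuration.

Each pipeline validates its configuration and input files up front, runs
the stages of one analysis (ChIP shift, BrU recovery, proteomics
enrichment), writes TSV outputs into the output directory, and finishes
with a machine-readable ``manifest.json`` recording parameters, the seed,
per-stage row counts, warnings, and a SHA-256 checksum of every output so
reruns can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import annotation, bruseq, coverage, pausing, profiles, proteomics

log = logging.getLogger(__name__)

__all__ = [
    "load_config",
    "run_chip_pipeline",
    "run_bruseq_pipeline",
    "run_proteomics_pipeline",
]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, pipeline: str, config: dict, seed: int):
        self.outdir = outdir
        self.doc: dict = {
            "pipeline": pipeline,
            "config": config,
            "seed": seed,
            "stages": {},
            "warnings": [],
        }

    def stage(self, name: str, **info) -> None:
        self.doc["stages"][name] = info
        log.info("stage %s: %s", name, info)

    def warn(self, message: str) -> None:
        self.doc["warnings"].append(message)
        log.warning(message)

    def finish(self) -> Path:
        outputs = {
            p.name: _sha256(p)
            for p in sorted(self.outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        }
        self.doc["outputs"] = outputs
        self.doc["manifest_hash"] = hashlib.sha256(
            json.dumps(self.doc, sort_keys=True, default=str).encode()
        ).hexdigest()
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.doc, fh, indent=2, sort_keys=True, default=str)
        return path


def _require_files(paths: list[str | Path]) -> None:
    missing = [str(p) for p in paths if p and not Path(p).exists()]
    if missing:
        raise FileNotFoundError("missing input file(s): " + ", ".join(missing))


def _load_chip_tracks(
    samples: list[dict], chrom_sizes: Mapping[str, int]
) -> dict[str, coverage.CoverageTrack]:
    """BED fragments → per-10M tracks, input-subtracted where an input is given."""
    tracks: dict[str, coverage.CoverageTrack] = {}
    for s in samples:
        frags = coverage.read_fragments_bed(s["fragments"], s.get("mapped_count"))
        track = coverage.normalize_per_10M(
            coverage.pileup(frags, chrom_sizes), frags.mapped_count
        )
        input_path = s.get("input")
        if input_path not in (None, "none"):
            in_frags = coverage.read_fragments_bed(input_path)
            in_track = coverage.normalize_per_10M(
                coverage.pileup(in_frags, chrom_sizes), in_frags.mapped_count
            )
            track = coverage.subtract_input(track, in_track)
        tracks[s["label"]] = track
    return tracks


def run_chip_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> Path:
    """Catalog selection → traveling ratios → shift classes → metaprofiles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = config["samples"]
    for s in samples:
        if "input" not in s:
            raise ValueError(
                f"sample {s.get('label')}: every ChIP sample needs an input track or explicit 'none'"
            )
    _require_files(
        [config["annotation"], config["chrom_sizes"]]
        + [s["fragments"] for s in samples]
        + [s["input"] for s in samples if s.get("input") not in (None, "none")]
    )
    manifest = _Manifest(outdir, "chip", config, seed)
    params = config.get("params", {})

    chrom_sizes = coverage.read_chrom_sizes(config["chrom_sizes"])
    catalog = annotation.load_tss_table(config["annotation"], config.get("annotation_format", "BED6"))
    selected = annotation.select_nonoverlapping(
        catalog,
        min_len=params.get("min_len", 3000),
        max_len=params.get("max_len", 100_000),
        flank=params.get("flank", 2000),
    )
    manifest.stage("select_nonoverlapping", n_in=len(catalog), n_out=len(selected))

    tracks = _load_chip_tracks(samples, chrom_sizes)
    manifest.stage("tracks", n_samples=len(tracks))

    mock_condition = config.get("mock_condition", "mock")
    mock_samples = [s["label"] for s in samples if s["condition"] == mock_condition]
    if not mock_samples:
        raise ValueError(f"no sample has the mock condition {mock_condition!r}")
    rank_sample = config.get("rank_sample", mock_samples[0])
    if rank_sample not in tracks:
        raise ValueError(f"unknown rank_sample {rank_sample!r}")

    n_top = min(params.get("n_top", 3000), len(selected))
    top = annotation.rank_top_bound(
        selected,
        tracks[rank_sample],
        window=tuple(params.get("rank_window", (-1000, 1000))),
        n=n_top,
    )
    top.write_bed6(outdir / "top_genes.bed")
    manifest.stage("rank_top_bound", n=n_top, rank_sample=rank_sample)

    preset = params.get("tr_windows", "RNAPII")
    windows = {"RNAPII": pausing.RNAPII_WINDOWS, "PAF1": pausing.PAF1_WINDOWS}.get(preset)
    if windows is None:
        windows = pausing.TRWindows(tuple(preset["promoter"]), tuple(preset["body"]))
    table = pausing.traveling_ratio_table(tracks, top, windows)
    table = pausing.normalize_tr(table, mock_samples)
    table.to_csv(outdir / "traveling_ratios.tsv", sep="\t", index=False)
    manifest.stage("traveling_ratios", rows=len(table), windows=windows.label)

    frac_rows = []
    for s in samples:
        frac, n_above, n_finite = pausing.fraction_above_one(table, s["label"])
        frac_rows.append((s["label"], s["condition"], frac, n_above, n_finite))
    pd.DataFrame(
        frac_rows, columns=["sample", "condition", "fraction_above_1", "n_above", "n_finite"]
    ).to_csv(outdir / "fraction_above_one.tsv", sep="\t", index=False)

    comparisons = [
        (s["label"], s["pair"]) for s in samples if s["condition"] != mock_condition and s.get("pair")
    ]
    if config.get("comparisons"):
        comparisons = [tuple(c) for c in config["comparisons"]]
    if comparisons:
        calls = pausing.classify_shift(table, comparisons)
        calls.to_csv(outdir / "shift_calls.tsv", sep="\t", index=False)
        counts = calls["class"].value_counts().to_dict()
        manifest.stage("classify_shift", comparisons=len(comparisons), **counts)

    span = tuple(params.get("span", (-2000, 5000)))
    bin_size = params.get("bin_size", 50)
    by_condition: dict[str, list[str]] = {}
    for s in samples:
        by_condition.setdefault(s["condition"], []).append(s["label"])
    metas = {}
    for condition, labels in by_condition.items():
        profs = [
            profiles.anchored_profile(tracks[lab], g, "TSS", span, bin_size)
            for lab in labels
            for g in top
        ]
        meta = profiles.meta_profile(profs, stat="mean", normalize="AUC", label=condition)
        meta.write_tsv(outdir / f"metaprofile_{condition}.tsv")
        metas[condition] = meta
    for condition, meta in metas.items():
        if condition == mock_condition:
            continue
        profiles.redistribution(meta, metas[mock_condition]).write_tsv(
            outdir / f"redistribution_{condition}.tsv"
        )
    manifest.stage("metaprofiles", conditions=sorted(metas))
    return manifest.finish()


def run_bruseq_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> Path:
    """Bin RPKM → median profile with zero baseline → absolute scaling → fronts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = config["samples"]
    _require_files(
        [config["annotation"], config["chrom_sizes"], config["nascent_levels"]]
        + [s["coverage"] for s in samples]
    )
    manifest = _Manifest(outdir, "bruseq", config, seed)
    params = config.get("params", {})
    chrom_sizes = coverage.read_chrom_sizes(config["chrom_sizes"])
    catalog = annotation.load_tss_table(config["annotation"], config.get("annotation_format", "BED6"))
    levels = bruseq.read_nascent_levels(config["nascent_levels"])

    mock_label = config.get("mock_sample")
    if mock_label is None:
        mocks = [s["label"] for s in samples if s.get("condition") == "mock"]
        if not mocks:
            raise ValueError("no mock sample in config")
        mock_label = mocks[0]

    span = tuple(params.get("span", (-5000, 25_000)))
    bin_size = params.get("bin_size", 500)
    length_bounds = tuple(params.get("length_bounds", (25_000, 50_000)))

    tracks = {
        s["label"]: coverage.read_bedgraph(s["coverage"], chrom_sizes, state="raw")
        for s in samples
    }
    mapped = {
        s["label"]: s.get("mapped_count") or int(tracks[s["label"]].total())
        for s in samples
    }

    # expression filter from the mock library: gene-level RPKM
    mock_track = tracks[mock_label]
    rpkm = {}
    for g in catalog:
        reads = float(mock_track.data[g.chrom][g.start : g.end].sum())
        rpkm[g.gene_id] = reads / ((g.length / 1000.0) * (mapped[mock_label] / 1e6))
    selected = annotation.select_expressed_by_length(
        catalog,
        rpkm,
        min_rpkm=params.get("min_rpkm", 0.05),
        tss_spacing=params.get("tss_spacing", 10_000),
        length_bounds=length_bounds,
    )
    if not len(selected):
        raise ValueError("no genes pass the expression/length/spacing selection")
    manifest.stage("gene_selection", n_in=len(catalog), n_out=len(selected))

    metas = {}
    for s in samples:
        label = s["label"]
        matrix = bruseq.bin_rpkm_matrix(tracks[label], selected, span, bin_size, mapped[label])
        matrix.write_tsv(outdir / f"bins_{label}.tsv")
        profile = bruseq.median_profile_zero_baseline(matrix)
        if label != mock_label:
            if label not in levels:
                raise ValueError(f"no nascent-transcription level for sample {label!r}")
            profile = bruseq.scale_absolute(profile, levels[label])
        profile.label = label
        profile.write_tsv(outdir / f"profile_{label}.tsv")
        metas[label] = profile
    manifest.stage("profiles", n=len(metas))

    rows = []
    threshold = params.get("front_threshold", 0.5)
    for label, profile in metas.items():
        if label == mock_label:
            continue
        d = bruseq.recovery_front(profile, metas[mock_label], threshold)
        rows.append((label, threshold, d))
    pd.DataFrame(rows, columns=["sample", "threshold", "front_bp"]).to_csv(
        outdir / "recovery_fronts.tsv", sep="\t", index=False
    )
    manifest.stage("recovery_fronts", rows=len(rows))
    return manifest.finish()


def run_proteomics_pipeline(config: dict, outdir: str | Path, seed: int = 0) -> Path:
    """Perseus-style clean → filter → impute → volcano (plus optional SILAC)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _require_files([config["protein_groups"]])
    manifest = _Manifest(outdir, "proteomics", config, seed)
    params = config.get("params", {})

    matrix = proteomics.read_protein_groups(config["protein_groups"])
    design = proteomics.GroupDesign(dict(config["design"]))
    n_raw = matrix.n_proteins
    matrix = proteomics.clean_and_log2(matrix)
    matrix = proteomics.filter_min_valid(matrix, design, params.get("min_valid", 4))
    manifest.stage("filter", n_raw=n_raw, n_kept=matrix.n_proteins)
    matrix = proteomics.impute_downshift(
        matrix,
        shift=params.get("impute_shift", 1.8),
        width=params.get("impute_width", 0.3),
        seed=seed,
    )
    groups = tuple(config.get("groups") or design.group_labels[:2])
    result = proteomics.group_ttest_volcano(matrix, design, groups)
    result.to_csv(outdir / "volcano.tsv", sep="\t")
    manifest.stage("volcano", rows=len(result), groups=list(groups))

    if config.get("silac_ratios"):
        ratios = pd.read_csv(config["silac_ratios"], sep="\t", index_col=0).iloc[:, 0]
        flags = proteomics.silac_enrichment(ratios, params.get("silac_threshold", 2.0))
        flags.rename("enriched").to_frame().to_csv(outdir / "silac_enriched.tsv", sep="\t")
        manifest.stage("silac", n_enriched=int(flags.sum()), n_total=len(flags))
    return manifest.finish()
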