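"""Calibration experiments: run the analysis on simulated cohorts with known
truth and measure how well it recovers the planted structure.

These functions define the package's standard self-checks — null
calibration of the shift statistics, classifier sensitivity under planted
pause release, recovery of the lesion-spacing decay from nascent-RNA
profiles, imputation moments, and volcano sensitivity. Each returns a
plain dict of numbers so the same experiments back both the test suite and
the reproduction script. All randomness flows from the single ``seed``
argument.

Problem sizes default to desk scale (hundreds of genes, 2×10⁵ fragments
per ChIP library, 10⁶ reads per nascent library): large enough that shot
noise does not dominate the measured statistics, small enough to run in
seconds.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import pausing, proteomics
from .annotation import GeneCatalog
from .bruseq import bin_rpkm_matrix, median_profile_zero_baseline, recovery_front, scale_absolute
from .coverage import normalize_per_10M, pileup
from . import simulate as sim

__all__ = [
    "null_shift_calibration",
    "release_recovery",
    "damage_decay_recovery",
    "imputation_calibration",
    "ttest_null_uniformity",
    "volcano_recovery",
    "pipeline_determinism",
]


def _chip_tracks(catalog, sizes, conditions, depth, base_seed, model=None, masks=None):
    model = model or sim.OccupancyModel()
    tracks = {}
    for i, (label, cond) in enumerate(conditions):
        frags = sim.simulate_chip_library(
            catalog,
            model,
            cond,
            depth,
            sizes,
            seed=base_seed + i,
            release_mask=None if masks is None else masks.get(label),
        )
        tracks[label] = normalize_per_10M(pileup(frags, sizes), frags.mapped_count)
    return tracks


def null_shift_calibration(
    n_genes: int = 300, depth: int = 200_000, n_pairs: int = 4, seed: int = 0
) -> dict:
    """Shift statistics on a no-UV cohort: Poisson replicates, no effect.

    With no UV effect a gene's normalized traveling ratio exceeds 1 with
    probability ~1/2, and with replicate-matched mock references the
    ALL_SHIFT frequency over k independent comparisons is ~0.5^k.
    """
    catalog, sizes = sim.simulate_catalog(n_genes, (5000, 9000), 6000, seed=seed)
    conditions = [(f"mock_{i}", sim.MOCK) for i in range(n_pairs)]
    conditions += [(f"null_uv_{i}", sim.MOCK) for i in range(n_pairs)]
    tracks = _chip_tracks(catalog, sizes, conditions, depth, base_seed=seed * 100 + 1)
    table = pausing.traveling_ratio_table(tracks, catalog, pausing.RNAPII_WINDOWS)
    mocks = [f"mock_{i}" for i in range(n_pairs)]
    table = pausing.normalize_tr(table, mocks)
    frac, n_above, n_finite = pausing.fraction_above_one(table, "null_uv_0")
    calls = pausing.classify_shift(
        table, [(f"null_uv_{i}", f"mock_{i}") for i in range(n_pairs)]
    )
    classified = calls[calls["class"] != "UNCLASSIFIED"]
    all_rate = float((classified["class"] == "ALL_SHIFT").mean())
    return {
        "fraction_above_one": frac,
        "n_finite": n_finite,
        "all_shift_rate": all_rate,
        "n_classified": len(classified),
        "n_comparisons": n_pairs,
    }


def release_recovery(
    n_genes: int = 300,
    depth: int = 200_000,
    f_high: float = 0.6,
    f_low: float = 0.4,
    n_pairs: int = 4,
    seed: int = 0,
) -> dict:
    """Classifier performance with planted pause release in half the cohort.

    Four UV replicates release a fraction ``f_high`` of the pause occupancy
    in a known responder subset; sensitivity and false-call rate are read
    against those truth labels. A single lower-release sample provides the
    dose-monotonicity readout of the mean normalized traveling ratio.
    """
    catalog, sizes = sim.simulate_catalog(n_genes, (5000, 9000), 6000, seed=seed)
    mask = {g.gene_id: (i < n_genes // 2) for i, g in enumerate(catalog)}
    uv_high = sim.ConditionSpec(
        label="uv_high", release_fraction=f_high,
        damage_spacing=sim.damage_spacing_for_dose(9.0),
    )
    uv_low = sim.ConditionSpec(
        label="uv_low", release_fraction=f_low,
        damage_spacing=sim.damage_spacing_for_dose(6.0),
    )
    conditions = [(f"mock_{i}", sim.MOCK) for i in range(n_pairs)]
    conditions += [(f"uv_{i}", uv_high) for i in range(n_pairs)]
    conditions += [("uv_low_0", uv_low)]
    masks = {label: mask for label, _ in conditions if label.startswith("uv")}
    tracks = _chip_tracks(catalog, sizes, conditions, depth, base_seed=seed * 100 + 7, masks=masks)
    table = pausing.traveling_ratio_table(tracks, catalog, pausing.RNAPII_WINDOWS)
    mocks = [f"mock_{i}" for i in range(n_pairs)]
    table = pausing.normalize_tr(table, mocks)
    calls = pausing.classify_shift(table, [(f"uv_{i}", f"mock_{i}") for i in range(n_pairs)])
    calls = calls.set_index("gene_id")
    released = pd.Series(mask)
    classified = calls["class"] != "UNCLASSIFIED"
    is_all = calls["class"] == "ALL_SHIFT"
    sensitivity = float(is_all[released & classified].mean())
    false_rate = float(is_all[~released & classified].mean())

    ntr = table.set_index(["sample", "gene_id"])["normalized_tr"]
    released_ids = [g for g, r in mask.items() if r]
    mean_high = float(ntr.loc["uv_0"].loc[released_ids].mean())
    mean_low = float(ntr.loc["uv_low_0"].loc[released_ids].mean())
    frac_uv, _, _ = pausing.fraction_above_one(table, "uv_0")
    return {
        "sensitivity": sensitivity,
        "false_all_shift_rate": false_rate,
        "mean_normalized_tr_high_dose": mean_high,
        "mean_normalized_tr_low_dose": mean_low,
        "fraction_above_one_uv": frac_uv,
        "n_released": int(released.sum()),
    }


def damage_decay_recovery(
    n_genes: int = 30,
    depth: int = 1_000_000,
    damage_spacing: float = 16_000.0,
    time_h: float = 3.0,
    elongation_speed: float = 4000.0,
    seed: int = 0,
) -> dict:
    """Recover lesion spacing and the recovery front from nascent profiles.

    Beyond the wave front the UV/mock profile ratio decays as exp(-x/L);
    an ordinary least-squares fit of log(ratio) against position returns
    the length constant, and the half-recovery front is compared with the
    wave position ``elongation_speed × time_h``.
    """
    catalog, sizes = sim.simulate_catalog(n_genes, (26_000, 40_000), 7000, seed=seed)
    uv = sim.ConditionSpec(label="uv", damage_spacing=damage_spacing)
    mock_track, _ = sim.simulate_bru_track(
        catalog, 0.0, sim.MOCK, sizes, elongation_speed, depth, seed=seed * 10 + 1
    )
    uv_track, level = sim.simulate_bru_track(
        catalog, time_h, uv, sizes, elongation_speed, depth, seed=seed * 10 + 2
    )
    span, bin_size = (-5000, 25_000), 500
    mats = {
        "mock": bin_rpkm_matrix(mock_track, catalog, span, bin_size),
        "uv": bin_rpkm_matrix(uv_track, catalog, span, bin_size),
    }
    prof_mock = median_profile_zero_baseline(mats["mock"])
    prof_uv = scale_absolute(median_profile_zero_baseline(mats["uv"]), level)

    front = recovery_front(prof_uv, prof_mock, threshold=0.5)
    expected_front = elongation_speed * time_h

    offsets = prof_mock.offsets
    centers = offsets + bin_size / 2.0
    fit_zone = (offsets >= expected_front + 2 * bin_size) & (offsets < span[1] - bin_size)
    ratio = prof_uv.bins[fit_zone] / prof_mock.bins[fit_zone]
    slope, _ = np.polyfit(centers[fit_zone], np.log(ratio), 1)
    fitted_L = -1.0 / slope
    return {
        "fitted_decay_length_bp": float(fitted_L),
        "true_decay_length_bp": float(damage_spacing),
        "front_bp": float(front),
        "expected_front_bp": float(expected_front),
        "bin_size": bin_size,
        "nascent_fraction": level.fraction,
    }


def imputation_calibration(n_missing: int = 100_000, seed: int = 0) -> dict:
    """Moments of the imputed distribution relative to the observed matrix.

    Reported on the scale of the observed s.d.: the mean offset converges
    to the downshift (−1.8) and the spread to the width (0.3).
    """
    rng = np.random.default_rng(seed)
    n_obs = 50_000
    n_rows = (n_obs + n_missing) // 4
    vals = rng.normal(23.0, 2.0, size=n_rows * 4)
    vals[rng.permutation(vals.size)[:n_missing]] = np.nan
    df = pd.DataFrame(
        vals.reshape(n_rows, 4), columns=["UV_1", "UV_2", "mock_1", "mock_2"]
    )
    df.index = [f"P{i}" for i in range(n_rows)]
    matrix = proteomics.IntensityMatrix(values=df, state="log2")
    observed = vals[np.isfinite(vals)]
    mu, sigma = observed.mean(), observed.std(ddof=0)
    out = proteomics.impute_downshift(matrix, shift=1.8, width=0.3, seed=seed + 1)
    imputed = out.values.to_numpy()[~np.isfinite(vals.reshape(n_rows, 4))]
    return {
        "mean_offset_sd": float((imputed.mean() - mu) / sigma),
        "width_sd": float(imputed.std(ddof=0) / sigma),
        "n_imputed": int(imputed.size),
    }


def ttest_null_uniformity(n_proteins: int = 10_000, seed: int = 0) -> dict:
    """KS test of t-test p-values against Uniform(0,1) on a null matrix."""
    matrix, _, design = sim.simulate_intensity_matrix(
        n_proteins=n_proteins, n_enriched=0, effect_log2=0.0, missing_max=0.0, seed=seed
    )
    res = proteomics.group_ttest_volcano(matrix, design, ("UV", "mock"))
    ks = stats.kstest(res["p_value"].to_numpy(), "uniform")
    return {"ks_p": float(ks.pvalue), "n_proteins": n_proteins}


def volcano_recovery(
    n_proteins: int = 2000,
    n_enriched: int = 100,
    effect_log2: float = 2.0,
    seed: int = 0,
) -> dict:
    """End-to-end label-free workflow sensitivity on planted enrichment.

    Runs filtering, imputation and testing on a matrix with realistic
    intensity-dependent missingness; a planted protein is recovered when
    p < 0.05 and log2 fold-change > 1. Proteins lost to the min-valid
    filter count as misses.
    """
    matrix, truth, design = sim.simulate_intensity_matrix(
        n_proteins=n_proteins, n_enriched=n_enriched, effect_log2=effect_log2, seed=seed
    )
    filtered = proteomics.filter_min_valid(matrix, design, min_valid=4)
    imputed = proteomics.impute_downshift(filtered, seed=seed + 1)
    res = proteomics.group_ttest_volcano(imputed, design, ("UV", "mock"))
    hit = (res["p_value"] < 0.05) & (res["log2_fc"] > 1)
    hit = hit.reindex(truth.index, fill_value=False)
    sensitivity = float(hit[truth].mean())
    fpr = float(hit[~truth].mean())
    return {
        "sensitivity": sensitivity,
        "false_positive_rate": fpr,
        "n_planted": int(truth.sum()),
        "n_tested": len(res),
    }


def pipeline_determinism(workdir: str | Path, seed: int = 0) -> dict:
    """Run the ChIP pipeline twice on one simulated study; compare checksums."""
    from . import pipelines

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    catalog, sizes = sim.simulate_catalog(10, (5000, 9000), 6000, seed=seed)
    catalog.write_bed6(workdir / "catalog.bed", sidecar=False)
    with open(workdir / "chrom.sizes", "w") as fh:
        for c, n in sorted(sizes.items()):
            fh.write(f"{c}\t{n}\n")
    model = sim.OccupancyModel()
    uv = sim.ConditionSpec(label="uv", release_fraction=0.6)
    samples = []
    for i, (label, cond) in enumerate([("mock_r1", sim.MOCK), ("uv_r1", uv)]):
        frags = sim.simulate_chip_library(catalog, model, cond, 30_000, sizes, seed=seed * 50 + i)
        frags.write_bed(workdir / f"{label}.bed")
        samples.append(
            {
                "label": label,
                "fragments": str(workdir / f"{label}.bed"),
                "input": "none",
                "condition": "mock" if label.startswith("mock") else "uv",
                "pair": None if label.startswith("mock") else "mock_r1",
            }
        )
    config = {
        "annotation": str(workdir / "catalog.bed"),
        "chrom_sizes": str(workdir / "chrom.sizes"),
        "samples": samples,
        "mock_condition": "mock",
        "params": {"n_top": 8},
    }
    checksums = []
    for run in ("run_a", "run_b"):
        pipelines.run_chip_pipeline(config, workdir / run, seed=seed)
        manifest = json.loads((workdir / run / "manifest.json").read_text())
        checksums.append(manifest["outputs"])
    return {"identical": checksums[0] == checksums[1], "n_outputs": len(checksums[0])}
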