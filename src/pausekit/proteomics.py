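"""Label-free and SILAC interaction-proteomics enrichment.

Implements the Perseus-style label-free workflow: drop contaminant /
reverse / identified-by-site hits, log2-transform LFQ intensities, require
full quantification in at least one experimental group, impute missing
values from a down-shifted normal distribution (missing values in pull-down
data are mostly below the detection limit, so the imputation distribution
sits 1.8 whole-matrix s.d. below the observed mean with 0.3 s.d. width),
and test groups with a two-sided equal-variance t-test for the volcano
plot. SILAC H/L ratios and iBAQ-based stoichiometry estimates are handled
by small dedicated helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IntensityMatrix",
    "GroupDesign",
    "read_protein_groups",
    "clean_and_log2",
    "filter_min_valid",
    "impute_downshift",
    "group_ttest_volcano",
    "silac_enrichment",
    "ibaq_stoichiometry",
]

FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


@dataclass
class IntensityMatrix:
    """Proteins × samples intensities with MaxQuant-style metadata flags."""

    values: pd.DataFrame  # index protein id, columns sample labels; NaN = missing
    flags: pd.DataFrame | None = None  # boolean columns from FLAG_COLUMNS
    ibaq: pd.DataFrame | None = None
    state: str = "linear"  # linear | log2

    def __post_init__(self) -> None:
        if self.state not in ("linear", "log2"):
            raise ValueError(f"unknown state {self.state!r}")
        if self.state == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("linear intensities must be non-negative")

    @property
    def n_proteins(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class GroupDesign:
    """Sample → experimental group assignment."""

    groups: Mapping[str, str]  # sample label -> group label

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    @property
    def group_labels(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen


def read_protein_groups(
    path: str | Path,
    lfq_prefix: str = "LFQ intensity ",
    ibaq_prefix: str = "iBAQ ",
    id_column: str = "Protein IDs",
) -> IntensityMatrix:
    """Read a MaxQuant proteinGroups-style TSV into an IntensityMatrix."""
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing column {id_column!r}")
    df = df.set_index(id_column)
    lfq_cols = [c for c in df.columns if c.startswith(lfq_prefix)]
    if not lfq_cols:
        raise ValueError(f"{path}: no columns starting with {lfq_prefix!r}")
    values = df[lfq_cols].rename(columns=lambda c: c[len(lfq_prefix):]).astype(float)
    flags = pd.DataFrame(index=df.index)
    for col in FLAG_COLUMNS:
        # MaxQuant marks flagged rows with "+"
        flags[col] = df[col].fillna("") == "+" if col in df.columns else False
    ibaq_cols = [c for c in df.columns if c.startswith(ibaq_prefix)]
    ibaq = (
        df[ibaq_cols].rename(columns=lambda c: c[len(ibaq_prefix):]).astype(float)
        if ibaq_cols
        else None
    )
    return IntensityMatrix(values=values, flags=flags, ibaq=ibaq, state="linear")


def clean_and_log2(matrix: IntensityMatrix) -> IntensityMatrix:
    """Drop flagged proteins and log2-transform; zero intensities become missing."""
    if matrix.state != "linear":
        raise ValueError("clean_and_log2 expects a linear matrix")
    values = matrix.values
    if matrix.flags is not None and not matrix.flags.empty:
        keep = ~matrix.flags.any(axis=1)
        values = values.loc[keep]
    with np.errstate(divide="ignore"):
        logged = np.log2(values.where(values > 0))
    ibaq = matrix.ibaq.loc[logged.index] if matrix.ibaq is not None else None
    return IntensityMatrix(values=logged, flags=None, ibaq=ibaq, state="log2")


def filter_min_valid(
    matrix: IntensityMatrix, design: GroupDesign, min_valid: int = 4
) -> IntensityMatrix:
    """Keep proteins quantified in >= min_valid replicates of at least one group."""
    for g in design.group_labels:
        if min_valid > len(design.samples(g)):
            raise ValueError(f"min_valid={min_valid} exceeds size of group {g!r}")
    keep = pd.Series(False, index=matrix.values.index)
    for g in design.group_labels:
        cols = design.samples(g)
        keep |= matrix.values[cols].notna().sum(axis=1) >= min_valid
    ibaq = matrix.ibaq.loc[keep] if matrix.ibaq is not None else None
    return replace(matrix, values=matrix.values.loc[keep], ibaq=ibaq)


def impute_downshift(
    matrix: IntensityMatrix,
    shift: float = 1.8,
    width: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> IntensityMatrix:
    """Replace missing log2 values with draws from a down-shifted normal.

    μ and σ are the mean and s.d. of *all* observed values in the matrix;
    each missing entry gets an independent draw from
    Normal(μ − shift·σ, (width·σ)²). Deterministic for a given seed.
    """
    if matrix.state != "log2":
        raise ValueError("impute_downshift expects a log2 matrix")
    vals = matrix.values.to_numpy(dtype=float)
    observed = vals[np.isfinite(vals)]
    if observed.size < 2:
        raise ValueError("matrix needs at least two observed values to impute")
    mu, sigma = observed.mean(), observed.std(ddof=0)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    missing = ~np.isfinite(vals)
    draws = rng.normal(mu - shift * sigma, width * sigma, size=int(missing.sum()))
    out = vals.copy()
    out[missing] = draws
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values)


def group_ttest_volcano(
    matrix: IntensityMatrix, design: GroupDesign, groups: tuple[str, str]
) -> pd.DataFrame:
    """Per-protein log2 fold-change and two-sided Student t p-value (a vs b).

    Returns a frame indexed by protein with columns log2_fc, p_value,
    neg_log10_p, and a Benjamini–Hochberg q_value column provided as an
    extra convenience (the volcano itself uses raw p-values).
    """
    a_label, b_label = groups
    a = matrix.values[design.samples(a_label)]
    b = matrix.values[design.samples(b_label)]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need at least two samples")
    if a.isna().any().any() or b.isna().any().any():
        raise ValueError("missing values present; impute before testing")
    fc = a.mean(axis=1) - b.mean(axis=1)
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    res = pd.DataFrame(
        {
            "log2_fc": fc,
            "p_value": p,
            "neg_log10_p": -np.log10(p),
        },
        index=matrix.values.index,
    )
    res["q_value"] = _benjamini_hochberg(res["p_value"].to_numpy())
    return res


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def silac_enrichment(ratios: pd.Series, threshold: float = 2.0) -> pd.Series:
    """Flag proteins with H/L ratio at least ``threshold`` (inclusive).

    H is the UV-irradiated (heavy) state, L the mock (light) state, so a
    ratio >= 2 marks at-least-2-fold stronger association after UV.
    """
    if (ratios <= 0).any():
        bad = ratios[ratios <= 0].index[0]
        raise ValueError(f"non-positive H/L ratio for {bad!r}")
    return ratios >= threshold


def ibaq_stoichiometry(
    ibaq: pd.DataFrame,
    bait: str,
    prey: Sequence[str],
    conditions: tuple[str, str],
) -> pd.DataFrame:
    """Bait-relative bound fractions per condition and their fold-change.

    iBAQ approximates molar amount, so iBAQ(prey)/iBAQ(bait) estimates the
    fraction of bait molecules bound by the prey in each condition;
    fold_change is fraction in the first condition over the second
    (e.g. UV over mock).
    """
    uv, mock = conditions
    for cond in conditions:
        if cond not in ibaq.columns:
            raise KeyError(f"condition column {cond!r} absent from iBAQ table")
        if ibaq.loc[bait, cond] <= 0:
            raise ValueError(f"bait {bait!r} has non-positive iBAQ in {cond!r}")
    rows = []
    for p in prey:
        f_uv = ibaq.loc[p, uv] / ibaq.loc[bait, uv]
        f_mock = ibaq.loc[p, mock] / ibaq.loc[bait, mock]
        rows.append((p, f_uv, f_mock, f_uv / f_mock if f_mock > 0 else np.inf))
    return pd.DataFrame(
        rows, columns=["prey", f"fraction_{uv}", f"fraction_{mock}", "fold_change"]
    ).set_index("prey")
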