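# Methods

This note documents the models and procedures pausekit implements, the
parameters that matter, the choices made where conventions were genuinely
open, and what the synthetic cohorts do and do not establish about real
data.

## Coordinates and signal

All intervals are 0-based half-open (BED convention). The TSS of a
minus-strand gene is `end − 1`; window offsets are always in transcribed
orientation, so offset 0 is the TSS base and positive offsets run into the
gene body on either strand. The signal unit is full-fragment per-base
depth: a fragment contributes 1 to every base it covers. We deliberately
do not reduce fragments to 5′ ends or midpoints — paired-end ChIP coverage
approximates fragment occupancy, and full-fragment depth reproduces that
without modelling insert sizes. Tracks carry an explicit normalization
state (`raw` → `per10M` → `input_subtracted`) and operations refuse
out-of-order transitions, which catches the most common pipeline mistake
(subtracting an unscaled input).

Depth normalization is to fragments per base per 10 million mapped
*fragments*; whether tag or fragment totals define the factor is a
convention, and we use fragment totals because that is the quantity a
deduplicated fragment BED actually carries. Input subtraction clips
negative values to zero: a background estimate exceeding the signal is
noise, and negative densities would corrupt every downstream ratio.

## Gene selection

Promoter-proximal analyses use genes of 3–100 kb (inclusive) whose span,
expanded by a 2-kb flank, touches no other annotated gene. The isolation
test runs against the *full* input catalog before length filtering — a
short neighbour that itself fails the length filter still contaminates a
profile, so it must still disqualify. Selection is idempotent and records
its parameters in a provenance dict serialized next to every written
catalog.

Nascent-RNA analyses select expressed genes (≥ 0.05 RPKM) in a length
class (default 25–50 kb) whose TSS is ≥ 10 kb from every other TSS in the
catalog. The spacing test uses all annotated TSSs, not just co-selected
ones, for the same contamination reason.

Ranking "top bound" genes uses mean density in a symmetric ±1 kb TSS
window on the unirradiated sample. The window is a package default, not a
community standard — published rankings rarely state theirs — so it is a
parameter, recorded in provenance, with ties broken lexicographically by
gene id so rankings are reproducible.

## Traveling ratios and shift classes

The traveling ratio divides early-body density by promoter-proximal
density. Two window presets are built in: RNAPII (promoter −750…+250,
body +250…+3000) and PAF1 (promoter −750…0, body 0…+1000), reflecting
that PAF1 repositioning after UV concentrates in the first kilobase while
RNAPII release reaches ~3 kb. Densities (per-bp means) rather than raw
window sums are used so a flat track gives TR = 1; the choice is
immaterial after cohort normalization because the window-length factor is
constant, and a test asserts the two conventions agree to 1e−12 after
normalization.

Normalization divides every ratio by the mean finite mock ratio, putting
the unirradiated cohort average at 1. Genes with zero promoter density
have an undefined (infinite) ratio and are excluded from distributions
and classification, counted separately as unclassifiable.

A gene shifts in a (UV, mock) comparison when TR_UV/TR_mock > 1 — a
strict threshold with no margin, the minimal reading of "above 1".
ALL_SHIFT requires the shift in every comparison. Mock references are
replicate-matched when the sample metadata pairs them; pairing makes the
comparison booleans independent, which is what gives the clean 0.5^k null
for the ALL_SHIFT rate. With a pooled mock reference the booleans share
mock noise and the null rate inflates; the package therefore treats
pairing as the default design.

## Metaprofiles

Per-gene TSS-anchored profiles default to span (−2000, +5000) at 50-bp
bins — wide enough to contain the 1–2 kb repositioning, fine enough to
resolve it. AUC normalization (divide by Σ bin × bin width) is applied to
the *averaged* profile, not per gene, so that a condition's profile is a
shape estimate unweighted by per-gene depth. Redistribution curves are
differences of AUC profiles and integrate to zero by construction; the
machine-precision tolerance (1e−9) on these identities is asserted in
tests. Length-normalized metagene profiles divide the body into equal
genomic fractions and weight partial bases by overlap, computed exactly
from the cumulative coverage.

## Ub-H2B profiles

H2B monoubiquitylation tracks elongation, so its gene-body profile is
informative only after removing the local background and restoring the
global scale that ChIP normalization destroys. Background is the single
profile bin containing −200 bp (a point estimate; one bin is the minimal
interpretation of "background just upstream of the TSS"), subtracted with
clipping at zero. The profile is then rescaled so its integral equals the
imaging-derived global Ub-H2B fraction for that condition (reference
condition = 1). The reference condition of the imaging fractions is
whatever the supplied scalar table used; the package consumes the table
as-is and records the condition labels, since recomputing microscopy
quantifications is out of scope.

## BrU-seq recovery model

Bin RPKM is reads-in-bin / (bin kb × mapped millions). The input track
holds per-base read-start counts (one count at a fragment's first base),
so a bin's read count is a plain sum — this makes the RPKM definition
exact and oracle-checkable rather than an approximation from smoothed
coverage. Coverage is exon-agnostic because nascent RNA covers intron
sequence.

The median (not mean) across genes is taken per bin — nascent-RNA
matrices are heavy-tailed and a few highly expressed genes would dominate
a mean. The upstream (−5 kb…TSS) mean is subtracted from all bins of the
median profile; negative bins are *retained*, unlike ChIP input
subtraction, because the zero baseline is a display convention and
clipping would bias the exponential fit below. Profiles are then
multiplied by the 5-EU-measured nascent fraction, converting shape to
amount.

The recovery model: lesions with mean spacing L bp attenuate elongation
as exp(−x/L); repair releases a recovery wave from the TSS moving at
speed v, so at time t the UV/mock profile ratio is 1 for x < v·t and
exp(−x/L) beyond. L anchors at 16 kb for a 7 J/m²-equivalent dose and
scales inversely with dose. v defaults to 4,000 bp/h — consistent with
full recovery of ~100-kb genes roughly a day after UV. The recovery front
estimator returns the largest distance d such that the profile ratio
stays ≥ a threshold (default 0.5) in every bin of (0, d]; with the
unshifted exponential beyond the front, the front is detectable once
v·t > L·ln 2 ≈ 11.1 kb, which the default 3-h timepoint (12 kb) clears.
The lesion spacing is recovered by ordinary least squares on log(ratio)
against position beyond the front.

## Proteomics workflow

The label-free path follows the standard Perseus sequence: remove
reverse / contaminant / identified-by-site entries, log2-transform (zeros
become missing), keep proteins fully quantified (4 of 4 by default) in at
least one group, impute missing values from Normal(μ − 1.8σ, (0.3σ)²)
with μ and σ computed over the *whole* observed matrix (per-column
statistics are available but off by default), and test with a two-sided
equal-variance Student t-test. No significance moderation (S0) and no
multiple-testing correction are applied to the primary output — the
volcano is read on raw p-values — though a Benjamini–Hochberg q-value
column is emitted as a clearly-supplementary convenience. SILAC
enrichment is an inclusive ≥ 2-fold H/L threshold. iBAQ stoichiometry
reports iBAQ(prey)/iBAQ(bait) per condition and its UV/mock fold-change.

## Synthetic cohorts

The generator produces the observable structure the analysis assumes,
with no claim of mechanistic fidelity:

- **Occupancy**: Gaussian pause peak at the TSS (height 20, s.d. 150 bp),
  flat body (1/bp), Gaussian TTS peak (height 5, s.d. 500 bp), uniform
  background (0.05/bp). Heights are relative; absolute depth is set by the
  requested library size.
- **UV release**: a fraction f of the pause mass moves into an
  exponentially decaying ramp over the first 2 kb (RNAPII-like) or 1 kb
  (PAF1-like) of the body; mass is conserved. The within-zone shape is
  unknown in reality; exponential decay is a modelling choice. f = 0.6 is
  the 9 J/m²-like default, 0.4 the 6 J/m²-like one.
- **Damage**: body occupancy and nascent signal attenuate as exp(−x/L),
  L = 16 kb at 7 J/m² scaling inversely with dose.
- **Genotypes**: CSB-KO and PAF1-depleted conditions forbid release
  (constructing them with f > 0 is an error); CSB-KO additionally applies
  a global scale loss; PAF1 depletion freezes the recovery wave near the
  promoter.
- **Sampling**: per-base Poisson counts with expectation proportional to
  the intensity, calibrated so the *mock* expectation equals the requested
  depth — conditions with global loss then yield proportionally fewer
  fragments, as real fixed-effort sequencing would after normalization.
  Fragments are fixed-length (200 bp) and centered on the sampled
  position, which keeps the analytic window means exact.
- **Proteomics**: protein baselines Normal(25, 2) in log2, replicate
  noise s.d. 0.3 (a typical LFQ CV), planted enrichment added to the UV
  group, missingness logistic in intensity (left-censoring), truth labels
  returned.

What the simulations do not contain: mappability and GC artifacts, PCR
duplicates, variable fragment sizes, expression heterogeneity between
genes, splicing structure, batch effects, or correlated missingness in
proteomics. Passing calibration on these cohorts shows the statistics are
implemented correctly and behave as designed under their own model; it
does not by itself validate the biological conclusions on real libraries.

## Calibration experiment sizes

The standard self-checks (pausekit.validation, also behind
`scripts/acceptance.py`) use cohorts of 300 genes at 2×10⁵ fragments per
ChIP library, 30 genes of 26–40 kb at 10⁶ reads per nascent library,
10⁵ imputed values, and 10⁴-protein null matrices. These sizes put the
binomial standard errors well inside the asserted 3-s.e. bands while
keeping a full run in seconds; they are package defaults, not limits.

## Known limitations

- The per-replicate shift criterion (threshold exactly 1, no pseudocount,
  replicate pairing) is the simplest consistent rule; published gene
  counts from equivalent analyses are sensitive to this choice and exact
  reproduction of any specific count is not expected without the original
  pairing metadata.
- `metagene_scaled` emits profiles in scaled bin coordinates; mixing them
  with fixed-bp profiles in one metaprofile is rejected rather than
  resampled.
- BAM and bigWig are intentionally not parsed; upstream alignment and
  dedup produce the fragment BED / bedGraph inputs this package consumes.
- The CLI's `--threads` flag is reserved; all stages are single-threaded.
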