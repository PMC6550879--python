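# Methods

This note documents the models and procedures implemented in `lhcoding`, the
parameter choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions adopted where the design was open.

## Trial structure and response detection

All spike times are seconds from trial onset. Trials last 3 s with a 250 ms
odor valve opening at 0.5 s and 4 repeats per (cell, odor). PSTHs use a
sliding 500 ms window advanced in 50 ms steps across 0–3 s (51 window
positions, half-open `[t, t + w)` bins); rates are trial-averaged Hz.

A cell-odor pair responds when its spike count in the 0.7–2.2 s test window,
pooled over trials, exceeds the count for the same cell's blank (solvent)
stimulus under an exact one-sided two-sample Poisson test. With equal
exposures the uniformly most powerful exact test conditions on the total:
under H0, `x ~ Bin(x + y, 1/2)`, so `p = P(Bin(x + y, 1/2) ≥ x)`; `x = y = 0`
gives `p = 1`. Each cell's family of odor p-values is Benjamini–Hochberg
adjusted (the family is per-cell because the blank is per-cell); pairs are
significant at adjusted `p < 0.01`. Single-trial detection repeats the test
per trial (FDR over odors within each cell × trial) at the more permissive
`p < 0.04`; the detection probability of a pair is the fraction of its trials
significant, so with 4 trials it lies in {0, ¼, ½, ¾, 1}. Reliability is the
mean detection probability over a cell's significant pairs, optionally
restricted to pairs with evoked rate ≥ 5 Hz.

Evoked rate is the PSTH maximum in 0.55–2.4 s; baseline is the 0–0.55 s rate.
Lifetime sparseness uses baseline-subtracted evoked rates clipped at zero
(the detection test is excitatory-only, so suppression is deliberately not
scored): `S = (1 − (Σr/N)²/(Σr²/N)) / (1 − 1/N)`, 0 for uniform tuning, 1 for
a single-stimulus response, undefined (NaN) for all-zero vectors.

## Correlation structure and shuffles

Per-odor PSTHs are concatenated into one vector per cell over a fixed odor
order; Pearson correlations are computed on raw (not z-scored) vectors, since
Pearson is already location/scale invariant per pair. Type-level matrices use
the mean concatenated profile per cell type. The shuffle control permutes
whole odor blocks — not individual bins — independently for each type,
because the quantity being destroyed is the across-type alignment of odor
labels, and per-type permutation preserves each type's own rates and tuning
breadth exactly. The correlation shift of a replicate is
`mean(original − shuffled)` over off-diagonal entries only (both diagonals
are 1 and would dilute the statistic; this is a deliberate deviation from a
literal all-entries mean and is noted here). Default 1000 replicates.

The sparse-subset comparison keeps only cell types with response probability
below 0.36 and recomputes the type matrix among survivors, so mean
cross-correlations are not inflated by broadly tuned types. The
breadth-vs-correlation relationship is an ordinary least-squares fit of
per-type mean off-diagonal correlation on per-type response probability,
reporting slope, adjusted R² and the two-sided slope p-value.

## Morphology similarity and cell-type recovery

Skeletons (7-column SWC; label 2 = axon, 3 = dendrite, unlabeled nodes
inherit the nearest labeled ancestor) are resampled to points at 1 µm
arc-length spacing; local tangents are the first principal direction of each
point's 5 nearest neighbours. The pairwise similarity of clouds a, b is

    S(a, b) = Σ_q exp(−d_q / σ) · |u_q · v_nn(q)|,

normalized by the self-score `S(a, a)` and symmetrized by averaging the two
directions, so self-similarity is exactly 1 and scores decay with rigid
translation. σ defaults to 3 µm. This is a deliberately simple
point-and-tangent score with the qualitative behavior of trained
log-odds-matrix scorers; any pairwise-similarity provider with the same
signature can be plugged in, and the clustering machinery is agnostic to it.

Clustering applies the Ward minimum-variance (Lance–Williams, ward.d2-style)
update directly to `1 − similarity` (or `1 − r` for physiology), with scipy's
lowest-index tie-breaking. Agreement with reference labels sweeps every
distinct merge height; at each cut, classification error is the minimum
mislabeling under optimal cluster-to-label matching (Hungarian assignment on
the confusion matrix) and agreement is the adjusted Rand index. The returned
cut minimizes classification error, breaking ties toward fewer clusters.
Pooled-vs-global analysis runs this per primary-neurite-tract pool and once
globally for both modalities; pools containing a single cell type are skipped
with a report.

## Category scoring and decoding

The scalar response of a type to an odor is the maximum baseline-subtracted
mean rate over six non-overlapping 250 ms bins covering 0.5–2.0 s. The bin
width is a package choice (the source analyses state only "6 bins following
onset"); it is configurable. AUC scores use Mann–Whitney pair counting with
half-credit ties and are normalized as `max(AUC, 1 − AUC)` so 0.5 always
means "no category information" regardless of response sign. Per type, the
unshuffled maximum over categories is compared against five odor-label
shuffles scored identically; a type is category-informative when its
unshuffled maximum strictly exceeds every shuffle maximum. Group contrasts
(LHON > PN, LHLN > PN) use one-sided Mann–Whitney U tests on the per-type
maxima.

Population PCA treats each (odor, time-bin) population vector as an
observation, centers, and eigendecomposes the covariance; component signs are
fixed by making the largest-magnitude loading positive. The adaptive divisive
normalization divides each odor's trajectory by its peak population-vector
norm plus a softening constant κ, defaulting to the median of the peak norms;
κ → ∞ recovers the unnormalized projections up to scale.

Decoding draws, per run, N cell types and one random cell per type; per time
bin, a one-vs-rest linear SVC is scored at each C in {10⁻⁸ … 10¹} with
stratified 4-fold cross-validation over the odor × trial responses (30 odors
× 4 trials = 120 labeled responses per cell per bin at the full panel). Runs
are split in half: the best C per bin is chosen on the first half and
accuracy is reported only from the second half, so tuning never sees the
evaluation samples. The shuffled control permutes each cell's responses
independently per bin across trials. Identity-task chance is 1/(number of
odors); category chance is the empirical majority-class frequency. The number
of runs per population size is not externally constrained; the package
default is 20, and the test suite and acceptance script use 6 with two time
bins and populations up to N = 3–4, which suffices to resolve the planted
LHON-vs-PN contrast.

## Anatomy scores

The overlap score between 1 µm point clouds is the all-pairs Gaussian sum
`Σ exp(−d²/2δ²)` with δ = 1 µm — an expected potential-synapse count. It is
symmetric, doubles exactly when one cloud's points are duplicated, and is
invariant under joint rigid motion. Neurons scoring below 6000 against the
PN-axon reference cloud are treated as skimming the LH; core output neurons
additionally need >50 % of dendritic cable inside the LH volume.
Cable-by-region tallies split segments exactly at axis-aligned region
boundaries and report the sum over regions of per-type means, so cell types
recorded at different frequencies contribute equally. The LH region and the
PN reference cloud are inputs (axis-aligned boxes and generated fixtures
here); template-brain registration is out of scope.

Supervoxels: Strahler order is computed per arbor, the highest-order trunk
segments are removed, and the remaining connected sub-branches are clustered
by the morphology similarity (Ward, 25 clusters per space — LH/dendritic and
target/axonal separately). Each cluster becomes a weighted isotropic-Gaussian
kernel density over its 1 µm points, every point weighted 1/(cluster point
count) so fields from clusters of different sizes are comparable (weights sum
to 1). The kernel bandwidth is not externally specified; the default is 5 µm,
the order of branch spacing in the synthetic fixtures, and is exposed in
config. Inclusion of an arbor in a field is the mean field density over the
arbor's points (a per-arbor mean implements "normalized by the total number
of points in each arbor"); the projection score of a type is the product of
its mean LH and target inclusions; the category-voxel score of a field is the
mean inclusion over types whose best AUC category matches. Display thresholds
default to the 90th percentile of each space's score distribution, standing
in for manually chosen cutoffs.

## Census estimator

For a tract with N profiles of which n were traced and k identified as LHNs,
the point estimate of the true LHN count K is `round(N·k/n)` (half-up;
fractional estimates are retained so that group subtotals need not equal sums
of rounded rows). The exact equal-tail interval at level 1 − α inverts the
hypergeometric distribution: K_lo is the smallest feasible K with
`P(X ≥ k) ≥ α/2` and K_hi the largest with `P(X ≤ k) ≥ α/2`, clipped to
`[k, N − (n − k)]`. Fully traced tracts (n = N) give zero-width intervals.
Exact inversion is conservative: simulated coverage of the 90 % interval runs
at ~95 %, never below the nominal level. Group totals use a Monte-Carlo
convolution of independent per-tract posteriors (uniform prior over each
tract's feasible K, hypergeometric likelihood), since sums of per-tract
interval endpoints are not a valid interval for the sum. The published
17-tract table is embedded as input data; its per-tract sample sizes were not
published for partially traced rows, so only fully traced rows are exactly
reproducible and the others are exercised through simulation.

## Synthetic generator: what it does and does not emulate

The generator plants the group statistics the analyses are designed to
resolve: baseline rates (PN 1.4 Hz, LHLN 1 Hz, LHON 0.1 Hz), response
probabilities (0.12 / 0.2 / 0.35 — the LHLN value is interpolated, as only
the PN and LHON figures are externally fixed), evoked peaks (21 / 16 / 14 Hz),
and stereotyped tuning: the odor set a type responds to is a deterministic
function of (type, panel, seed), shared by all cells of the type, with
category-bias multipliers on selection probability for flagged odors.
Response-magnitude variability across animals is a per-cell log-normal gain
(σ = 0.3) plus per-trial log-normal jitter (σ = 0.2). The evoked rate is a
rectangular bump (onset 50 ms after the valve, duration 500 ms) with 50 ms
Gaussian-smoothed edges, sampled exactly as uniform-plus-Gaussian; this
matches the analysis windows without claiming kinetic realism. Skeleton sets
are jittered copies of per-type prototype trees (dendrite in an LH sub-box,
axon into a target box); odor panels assign one category flag per odor,
balanced across the six categories.

Not emulated: inhibitory/suppressed responses (the detection test is
excitatory-only), adaptation and temporal response diversity, correlated
noise across simultaneously active cells, receptor chemistry, and realistic
arbor geometry. Passing tests therefore demonstrate that the analysis chain
recovers planted structure of the stated kind at desk scale — not that real
recordings would yield the published effect sizes, which depend on the real
data.

## Numerical conventions and degenerate inputs

* PSTH bins are half-open; a pair with no presented trials is a missing
  value, not zero.
* `x = y = 0` gives p = 1; empty FDR families pass through unchanged.
* Zero-variance rows are excluded from correlation matrices with a report;
  fewer than two valid rows is an error.
* Empty point clouds score overlap 0 with a warning; dotprops construction
  rejects empty clouds.
* All-zero response vectors have undefined sparseness (NaN), and cells with
  no significant pairs have missing reliability.
* Every stage consumes an explicit seed; the pipeline fans a single global
  seed into named per-stage substreams (CRC-keyed `SeedSequence`), so stages
  are individually reproducible and identically seeded runs are byte-identical.

## Problem sizes

The default test-suite and acceptance runs use 36-odor panels for detection
statistics (200 null cells for the FDR audit), 6–30 odors elsewhere, 2000
simulated tracts for CI coverage, 1000 shuffle replicates, and decoding with
6 runs × 2 bins at N ≤ 4 over a 6-point C grid. These sizes were chosen so
the full suite completes in about a minute while leaving every statistical
assertion with comfortable Monte-Carlo margins.
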