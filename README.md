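# lhcoding

Analysis pipeline for odor coding and quantitative neuroanatomy in the
*Drosophila* lateral horn (LH), the higher olfactory centre linked to innate
behavior. The package is aimed at systems neuroscientists working with
trial-structured in-vivo patch-clamp recordings and single-neuron skeleton
data who want to ask: do third-order lateral horn neurons (LHNs) form
stereotyped cell types, and do they encode odor *categories* better than
their projection-neuron (PN) inputs?

It covers the full quantitative chain:

* **Response detection** — sliding-window PSTHs (500 ms window, 50 ms step
  over 0–3 s trials) and an exact one-sided two-sample Poisson test of odor vs
  blank spike counts in the 0.7–2.2 s window. With equal exposure the test is
  conditional-binomial: `p = P(Bin(x+y, 1/2) ≥ x)`. Per-cell families of odor
  p-values are Benjamini–Hochberg adjusted; a pair is significant at adjusted
  `p < 0.01` (single trials at `p < 0.04`), giving per-pair detection
  probabilities, reliability, tuning breadth and lifetime sparseness
  `S = (1 − (Σr/N)²/(Σr²/N)) / (1 − 1/N)`.
* **Population correlation** — concatenated-PSTH cell-odor matrices, Pearson
  correlation at the cell and the cell-type level, odor-label shuffles (whole
  odor blocks permuted independently per type, 1000 replicates) yielding the
  correlation shift, sparse-subset comparisons (`p(response) < 0.36`) and a
  breadth-vs-correlation regression.
* **Cell-type classification** — a simplified point-and-tangent morphology
  similarity (`exp(−d/σ)·|u·v|`, σ = 3 µm, self-normalized and symmetrized),
  Ward clustering of `1 − similarity` (or `1 − r` for physiology), and a cut
  sweep scored by adjusted Rand index and Hungarian-matched percent correct,
  per primary-neurite-tract pool and globally.
* **Category coding** — per-type ROC/AUC scores for six chemical categories
  (alcohol, aldehyde, amine, carboxyl, ester, phenyl) with five shuffled
  controls, one-sided Mann–Whitney group comparisons, PCA population
  trajectories with adaptive divisive normalization, and a linear SVC
  population-decoding harness (C grid 10⁻⁸…10¹, 4-fold stratified CV,
  half-split C selection).
* **Anatomy scoring** — arbor overlap scores
  `Σ_s Σ_k exp(−d²/2δ²)` with the 6000 exclusion threshold, core-LHON
  selection (>50 % dendrite in the LH), exact cable-by-region tallies, and
  supervoxel maps: 25 Ward-clustered sub-branch sets (Strahler trunk removed)
  turned into weighted Gaussian kernel-density fields with inclusion /
  projection / category scores.
* **EM census** — hypergeometric estimation of LHN counts per primary-neurite
  tract from partial tracing, with exact equal-tail 90 % confidence intervals
  and Monte-Carlo convolution for group totals; the published 17-tract table
  ships as input data.

A synthetic-data generator reproduces the statistical structure of the
recordings (PN baseline 1.4 Hz, 12 % response probability, 21 Hz evoked peaks;
LHON 0.1 Hz, 35 %, 14 Hz; LHLN in between; 4 trials of 3 s with a 250 ms valve
opening at 0.5 s; stereotyped per-type tuning with per-cell log-normal gain),
so every stage runs end-to-end with no external downloads.

## Worked example

```python
from lhcoding import synthetic, spikes, census

panel = synthetic.gen_odor_panel(36, seed=1)          # 6 categories × 6 odors + blank
templates = [synthetic.pn_template(),
             synthetic.lhon_template(category_bias={"amine": 3.0})]
ds = synthetic.gen_spike_dataset(templates, 10, panel, seed=1)

rt = spikes.detect_responses(ds)                      # exact Poisson test + FDR
print(spikes.summarize_rates(ds, rt).round(2))
print(rt.cell_breadth().groupby(ds.cell_meta()["group"]).mean().round(3))

est = census.estimate_tract_lhns(census.TractSample("PV2", 193, 60, 29, "LHLN"))
print(est)
```

prints

```
       baseline  all_responses  significant_responses  n_cells
group
LHON       0.24           5.00                  12.49       10
PN         1.48           4.33                  24.65       10

group
LHON    0.375
PN      0.064

CensusEstimate(tract='PV2', estimate=93, estimate_raw=93.28, lo=76, hi=111,
               level=0.9, cls='LHLN')
```

The recovered group contrast matches the generator's planted physiology: LHONs
are ~10× quieter at baseline, respond to ~3× more odors (breadth 0.375 vs
0.064) but with lower evoked rates than PNs. The census line reads: of 193
profiles in the tract, 60 were traced and 29 were LHNs, giving an estimated
93 LHNs with a 90 % interval of 76–111.

The same stages are available from the shell:

```bash
lhcoding run --seed 1 --out results/          # full synthetic pipeline
lhcoding worked-checks                        # printed-arithmetic audit
lhcoding census --out census.json             # published tract table census
lhcoding detect-responses --spikes spikes.csv --panel odors.csv --out responses.csv
```

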