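# Methods

`crcsubtype` implements the computational workflow used to molecularly
characterize colorectal-cancer (CRC) preclinical model systems — 2D
monolayer cultures, 3D spheroids and subcutaneous xenografts derived from
established CRC cell lines — and to analyze bioluminescence-based spheroid
cytotoxicity assays. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data generators do
and do not emulate.

## Quantile-rank iCMS scoring

Input is a gene-level log2 expression matrix; probe-level arrays are first
mean-collapsed (each gene's value is the arithmetic mean of its probe
sets' values, per sample). For each sample the genes are ranked ascending
and the rank divided by the number of genes, giving quantile ranks in
(0, 1]. Ties receive the average rank. This convention keeps every rank
strictly positive, so the ratios in score A below are always defined.
Ranks are computed over all measured genes by default (a flag restricts
them to the marker-set union).

Four marker gene classes define the two intrinsic epithelial tumor-cell
states: iCMS2_up (2U), iCMS2_down (2D), iCMS3_up (3U), iCMS3_down (3D).
With Mq* the mean and Sq* the sum of a sample's quantile ranks over a
class (after intersecting the class with the measured genes; coverage is
logged, absent genes are dropped, never imputed):

    A = (Mq2U / Mq2D) − (Mq3U / Mq3D)
    B = (Sq2U − Sq2D) − (Sq3U − Sq3D)

Positive scores point to iCMS2, negative to iCMS3. Each score yields a
call by sign; the consensus is the shared call when the two agree and
`discordant` otherwise. A score of exactly zero supports neither class,
so it forces a discordant consensus with a `zero_score` flag rather than
fabricating a call. Score B is reported on raw sums exactly as defined,
although with unequal class sizes it is scale-dependent; a normalized
variant (sums divided by class size) exists behind a flag but is never
the default.

Because only within-sample ranks enter, both scores are invariant under
any strictly increasing per-sample transform of expression — the property
the acceptance suite verifies bit-exactly.

## Nearest-template prediction

Each class defines an indicator template over the lexicographically
ordered union of marker genes present in the matrix. A sample's profile
over those genes is mean-centered (so distances respond to which genes
sit above or below the sample's own average; this also makes the result
invariant to additive shifts) and compared to each template by cosine
distance d = 1 − cos, d ∈ [0, 2]. Euclidean distance on the same centered,
norm-scaled profile is available behind a flag. The call rule is purely
ordinal:

    D2U < D2D and D3U > D3D → iCMS2
    D2U > D2D and D3U < D3D → iCMS3
    anything else           → unstable

Inequalities are strict: an exact tie routes to `unstable`, and
perturbing a tie can flip between a class call and `unstable` but never
directly between classes. (The protocol this rule derives from prints the
second comparand as a self-comparison, "D3U > D3U"; D3D is the evident
intent.) An optional gene-label permutation p-value is provided as a
diagnostic but never enters the call.

When both the scoring route and NTP are run, the cross-route agreement
rate is reported over samples that received a class call from *both*
routes (discordant and unstable excluded), together with the size of that
subset. Under the synthetic cohort below, shifts are planted only on the
sample's own label classes, so the opposite class's two distances differ
only by noise and roughly half the samples are `unstable` by the strict
rule; concordance among mutually classified samples is the informative
quantity.

## Model-system analysis

*Gene filter.* Per feature, a one-way F-test across sample groups
(model systems by default), Benjamini–Hochberg adjustment across
features, and log2 fold changes computed as differences of group means on
the log2 scale against a named baseline (2D cultures, or normal tissue
for tumor-vs-normal contrasts). A feature passes when q < FDR threshold
AND its contrast fold changes exceed the cut — under "any contrast" by
default, with an `all` option. Constant features have undefined F and are
excluded with a warning. Typical threshold pairs: FDR < 1e-4 with
|log2FC| > 5 for tumor-vs-normal; FDR < 0.01 with |log2FC| > 1.5 or > 2
for the model-system comparison, the stricter cut giving a nested,
strictly smaller gene set.

*Pattern taxonomy.* Per gene, mean expression per model system gives two
steps: step1 = spheroid − 2D, step2 = xenograft − spheroid. With
threshold δ (default 0.25 log2 — the taxonomy's source states no numeric
criterion, so the threshold is explicit and configurable):
both steps > δ → increasing; both < −δ → decreasing; first step beyond
±δ and second within ±δ → increase/decrease-then-plateau; else none.
Genes outside `none` are "characteristic" — evidence that spheroids carry
xenograft-like expression traits — and their fraction is reported.

*Similarity.* Per cell line, Pearson correlation between per-system mean
profiles over a chosen gene set; the verdict is which in vitro system
(spheroid vs 2D) correlates better with the xenograft.

*Clustering.* Agglomerative clustering with 1 − Pearson distance and
average linkage by default (configurable); observations are presented in
id-sorted order so equal-distance merges resolve deterministically by
smallest id. The dendrogram is exported as Newick text.

*Marker screen.* Two-group ranking by log2FC = mean(A) − mean(B),
descending with gene-id tie-break, with the linear fold 2^log2FC
alongside — the screen that surfaces a CAV1-like oxaliplatin-resistance
marker with a several-hundred-fold difference.

## Dose–response analysis

*QC.* Day-0 titration of seeded cells (150–20,000): least-squares line
signal ~ cells with R² as a configurable gate. Luminescence must track
cell amount before dose–response readouts are meaningful.

*4PL fit.* Treated-well signals are divided by the same-condition dose-0
mean at the endpoint (day 7), then fitted with

    R(d) = bottom + (top − bottom) / (1 + 10^(hill·(log10 d − log10 IC50)))

by least squares, parameterized in log10 IC50, with multi-start initial
values on a log10-dose grid spanning the dosed range and bounds keeping
hill positive. IC50 is the *relative* convention — the curve midpoint,
R(IC50) = (top + bottom)/2 exactly. With fewer than four distinct doses
the asymptotes are pinned to the data envelope. The IC50 SD is the
standard deviation of IC50s from refitting each replicate's own wells
(the dispersion a replicate-level test needs); the pooled-fit value is
the headline IC50. The dilution series must bracket the expected IC50 on
both sides — an IC50 at the edge of the dosed range leaves the near
asymptote unidentified and inflates the estimate's error; the default
synthetic design (3-fold serial dilution from 10 µM, 8 doses) samples
both plateaus for sub-µM IC50s.

*Welch comparison.* 2D vs spheroid IC50s are compared by Welch's
unequal-variance t-test on log10 per-replicate IC50s (IC50s are positive
and right-skewed across replicates, so the log scale is natural), with
Welch–Satterthwaite degrees of freedom and a two-sided p; significance at
α = 0.05 by default. The test's empirical size is verified by simulation
(0.05 ± 0.01 at 10,000 null replicates, n = 8/8).

## Synthetic-data generators

The study's microarrays and plate reads are not deposited under a usable
accession, so every stage runs on generators with planted ground truth.

*Cohorts* (`simulate_cohort`): gene × sample log2 matrix = baseline mean
(7.0) + planted shifts + N(0, σ²). An iCMS2 sample gets +Δ on the 2U
genes and −Δ on 2D; an iCMS3 sample likewise on 3U/3D. Defaults Δ = 1.0
log2, σ = 0.5 log2, 30 genes per class within 500, 100 samples per label
— a separable but noisy regime. Gaussian log2 noise models a microarray;
count noise, probe-level effects and normalization artifacts are not
emulated, so passing tests show the scoring logic recovers planted rank
structure, not that it is robust to RMA-level artifacts.

*Model systems* (`simulate_model_systems`): per cell line a random gene
baseline (SD 1.0 log2) shared across its three systems, plus per-category
step patterns: monotone categories step 1.2 log2 per transition, plateau
categories a single 1.8 log2 first step; composition 64/25/3/18 within
152 genes, 4 cell lines × 3 systems × 2 replicates, noise SD 0.2 log2.
Because the spheroid offset is intermediate by construction, spheroids
correlate more strongly with xenografts than 2D does — the planted analog
of the biological claim, not evidence for it. An optional `MARKER` gene
carries a +8.64 log2 shift (≈ 399-fold) in "resistant" cell lines.

*Plates* (`simulate_plate`): signal = control counts × true 4PL response
× (1 + N(0, CV²)), truncated at zero, with 8 replicate wells per dose,
dose-0 controls, and a day-0 seeded-cells titration. Default CV 5%.

All generators are deterministic under a fixed seed, and changing the
seed changes values but never the planted truth assignments.

## Pipeline

`run_pipeline` executes io → scoring → NTP → model-system →
dose–response per a YAML config, writing per-stage TSVs, a Newick
dendrogram, and a JSON summary. One config seed fans out to per-stage
seeds by fixed offsets; a rerun with the same config is byte-identical.
Existing outputs are never overwritten without `force`.

## Problem sizes and limitations

The shipped checks use cohorts of 200 samples × 500 genes, 152-gene
model-system fixtures, 1000 simulated plates for IC50 error and 10,000
null replicates for test size — sizes at which the statistical properties
(≥95% planted-label recovery, <5% median IC50 error at 5% CV, Welch size
within ±0.01 of nominal) are stable across seeds. Known limitations: no
probe-level/RMA emulation; no mouse-stroma contamination model for
xenograft profiles; NTP confidence (permutation FDR) is diagnostic only;
the external CMS classifiers (CMScaller, CRCassigner) are out of scope;
and filter pass counts on synthetic data are structural analogs of the
original 749/152/51 sets, not reproductions of them.
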