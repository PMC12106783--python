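# Methods

`sclcmet` implements the computational arms of a small cell lung cancer
(SCLC) metastasis-driver study as a reusable, tested pipeline: candidate
nomination from bulk RNA-seq, pre-ranked gene-set enrichment, single-cell
malignant-cell identification, FOXA2 co-expression ranking, IHC biomarker
cutpoint/survival analysis, and ATAC/ChIP peak-to-gene utilities.  Every
stage can be exercised end to end on the bundled synthetic-data generators,
which plant known structure so each stage has a recovery oracle.

## Bulk differential expression and nomination

Counts are modeled per gene as negative binomial with variance
`mu + alpha * mu^2`.  Size factors are the median-of-ratios estimator
(per-sample median, over genes expressed in all samples, of
count / across-sample geometric mean), rescaled so their geometric mean is
one.  For a two-group contrast we fit, per gene, a log-link NB GLM with an
intercept, a group indicator and a log-size-factor offset, by iteratively
reweighted least squares vectorized across genes.  The dispersion is a
within-group method-of-moments estimate, `(s^2 - m) / m^2` pooled across
groups with `n_i - 1` weights and floored at `1e-8`; no empirical-Bayes
shrinkage is applied, since nomination is threshold-based recovery rather
than numerical replication of a specific tool.  The Wald statistic
(coefficient / SE from the Fisher information) is referred to a **t
distribution with `n_samples - 2` degrees of freedom** rather than a normal:
with a plug-in dispersion estimated from ~16 samples, the normal reference
is measurably anticonservative (empirical size ~0.07 at nominal 0.05 in
null simulations), while the t reference restores calibration (~0.05).
Genes with fewer than 10 total counts are not tested (reported with
log2FC 0, p 1); Benjamini–Hochberg adjustment runs over tested genes only.

Nomination intersects two contrasts — met-associated primary vs never-met,
and metastasis vs never-met — keeping genes with fold change above 4 (or
below 1/4; a "negative fold change" for count ratios is read as symmetric
down-regulation) and adjusted p below 0.05 in **both**, with strict
inequalities at both gates, then restricts to transcription factors,
ordered by mean |Wald| across the contrasts.  An alternative preset
(FC 1.5, FDR 0.01) matching a more permissive differential-expression
convention is exposed as `STANDARD_PRESET`.

## Pre-ranked gene-set enrichment

Genes are ranked by `-log10(p) * sign(log2FC)` (p floored at 1e-300; ties
broken by |log2FC| then gene id).  The enrichment score is the signed
extremum of the weighted Kolmogorov–Smirnov running sum with weight
exponent 1 (hits advance by `|score|^w / sum_hits |score|^w`, misses retreat
by `1/(N - N_hits)`).  The null is gene-set permutation — random same-size
sets drawn from the ranked universe — because the input is a pre-ranked
list and phenotype labels are not available at this stage.  NES divides the
ES by the mean |null ES| of matching sign; p-values use the add-one
estimator over same-sign null draws (so p >= 1/(n_perm+1)); BH adjustment is
applied across all sets tested in one call, with adjusted p <= 0.05 as the
default significance gate.

## Single-cell pipeline

Cells with fewer than 200 detected genes or more than 40% mitochondrial
counts are removed (boundary cells retained, matching the strict removal
conditions).  Counts are scaled to the median library size and
log1p-transformed.  Highly variable genes are ranked by variance
standardized against a degree-2 polynomial trend of log10 variance on
log10 mean, with per-cell standardized values clipped at sqrt(n_cells); the
trend variance is floored at the Poisson expectation (variance = mean),
which guards the fit when the mean range is narrow.  Compartments
(epithelial / immune / fibroblast / endothelial) are assigned per cell by
the argmax of binned-control signature scores over marker sets; cells with
no marker expression or a sub-threshold winning margin stay unassigned.

The copy-number signal is a simplified relative-expression smoother:
log2(scaled count + 1) minus the reference-cell mean, clipped at ±3,
moving-average smoothed over 51 genes within each chromosome (window
shrunk and logged on short chromosomes), median-centered per cell, and
mean-aggregated into half-open 10 Mb bins.  Cells are clustered on this
matrix (PCA to min(50, bins) components, cosine k=15 nearest-neighbor
graph, seeded Louvain).  A cluster is called malignant when its burden
(mean over cells of the mean squared bin value) exceeds `theta = 3` times
the median burden of non-epithelial-dominated clusters **and** its
epithelial fraction is at least 0.9.  This automated rule replaces what is
otherwise a manual inspection step; the thresholds are emitted in the
output metadata, and a per-cell burden fallback (flagged) covers the
degenerate single-cluster case.

## FOXA2 association

Malignant cells are FOXA2+ iff the raw FOXA2 count is positive.  Patients
enter the association analysis with **more than** 200 malignant cells and
at least 10% FOXA2+ cells.  Within each patient's malignant cells,
expression is normalized to the patient's median library size,
log1p-transformed and standardized gene-wise to mean 0 / variance 1; the
standardized FOXA2 vector is regressed on the standardized HVG matrix with
an L2 penalty, solved in closed form via the normal equations (dual form
when cells < genes).  The penalty strength is lambda = 1.0 on standardized
data — the value is not critical because downstream use is rank-based
recovery, not coefficient interpretation.  Per-gene coefficients are
combined across patients as a one-sample Z, `z = mean / (sd / sqrt(P))`
with the sd floored at 1e-12 (floored genes flagged degenerate).  The top
100 genes by z are re-ranked by their bulk Pearson correlation with FOXA2
(computed on log2 normalized counts + 1); genes missing from bulk are
flagged and placed last.  HVGs are selected globally by default, with the
query gene always excluded from the predictors.

Signature scores are binned-control scores: genes are split into 25
equal-size bins by mean normalized expression, each set gene draws 50
seeded control genes from its bin (set genes excluded from the pool), and
the score is the set mean minus the pooled-control mean.  FOXA2+/− score
comparisons use the one-sided Mann–Whitney U test (positive group
greater), computed from midrank sums with exact enumeration when
`n1*n2 <= 100` and the tie-corrected normal approximation otherwise.

## Biomarker cutpoint and survival

The H-score is `sum(level * percent)` over staining levels 0–3 (range
0–300); percentage vectors must sum to 100.  The cutpoint maximizing
sensitivity + specificity for recurrence is found by exhaustive search over
midpoints between consecutive distinct scores, with a positive call at
score >= cutpoint and ties broken toward the smallest cutpoint.  High score
is treated as high risk throughout; the search does not auto-flip
direction.  Because candidates are midpoints, a reported cutpoint may sit
anywhere within the data gap containing the underlying threshold — the
same confusion tables result.  Kaplan–Meier curves and the two-group
log-rank test are delegated to lifelines; `event = False` denotes right
censoring, and a cohort with no events returns chi2 = 0, p = 1, flagged.

## Peak utilities

All coordinates are 0-based half-open.  Peaks on a chromosome merge when
their inter-interval gap is at most 500 bp (standard interval-merge
semantics, applied transitively); the merged summit and statistics follow
the member with the largest |log2FC|, ties toward the leftmost.  The summit
atlas takes ±250 bp around each (pre-merge) summit, clipped at chromosome
bounds — upper clipping requires a chromosome length and raises when it is
missing; flank 0 degenerates to a width-1 window.  Peaks overlapping a
blacklist interval by >= 1 bp are dropped whole.  Peak-to-gene assignment
gives intragenic peaks to the containing gene (distance 0; among multiple
overlaps, the gene whose TSS is closest to the peak midpoint, ties broken
lexicographically) and intergenic peaks to the nearest TSS on the same
chromosome by linear distance from the peak midpoint; TSS is `start` on the
plus strand and `end - 1` on the minus strand.  Gene-level scores take the
signed log2FC of the assigned peak with the largest magnitude, producing a
valid input for pre-ranked enrichment.

## Synthetic data: what it emulates, and what it does not

One root seed feeds independent sub-streams per generator, so outputs are
bit-reproducible and adding a generator never perturbs another.  The
genome is three 120 Mb chromosomes with genes placed uniformly (36 bins of
10 Mb — enough for CNV clustering without genome scale).  Planted
structures are returned in a `GroundTruth` object and never written into
the data files the pipeline consumes.

**Bulk.**  Three cohorts (never-met 8, met-associated primary 5,
metastasis 25 samples) with log-normal(0, 0.2²) library-size factors and
NB counts at dispersion `alpha = 0.02`.  Eight planted driver TFs are
shifted by log2FC 2.5 in both met cohorts only, and are placed on
well-expressed genes (base mean 100–500).  These defaults come from a
power analysis at the fixed design: the log2FC standard error for the
5-vs-8 contrast is roughly `sqrt((1/mu + alpha) (1/5 + 1/8)) / ln 2`; at
`alpha = 0.02` and `mu >= 100` a planted 2.5 clears the log2FC > 2 gate
with per-driver miss probability ~2e-4, so exact recovery of all eight
drivers is the expected outcome, while at `alpha = 0.1` (used by the null
calibration runs) misses would be common.  A cohort-independent latent
factor (loading 0.8 in log2) is shared by FOXA2 and the planted module
genes — both given base means 50–200, since a correlation is only
measurable where counts rise above noise at N = 38 samples.

**Single cell.**  Default five patients × 1,000 cells; compartments drawn
from a 50/30/10/10 epithelial/immune/fibroblast/endothelial mix, each with
a disjoint 30-gene marker program (×20).  80% of epithelial cells per
patient form a malignant clone whose genes inside the configured CNV
segments scale by `2^shift`; the default karyotype alters five arm-scale
segments across all three chromosomes because SCLC genomes are heavily
aneuploid — an isolated single-segment alteration is not a realistic SCLC
clone and would under-drive the burden statistic.  Half of malignant cells
are FOXA2+: they receive `1 + NB(4 * activity)` FOXA2 counts (positivity
holds by construction; FOXA2 itself is tightly regulated, dispersion 0.05),
where the latent activity (truncated normal) also scales the 10 planted
module genes by `2^(module_effect * z(activity))`.  The activity-linked
module + FOXA2 mass is balanced against a single highly expressed
housekeeping-like gene, holding each cell's expected total output
independent of the FOXA2 program: without this, library-size normalization
couples every null gene to FOXA2 (the cross-patient Z amplifies any
systematic correlation by ~sqrt(n_cells × P), so even r ≈ −0.001 breaks
null-Z normality).  For the same reason the per-cell depth factor is
log-normal(0, 0.12²).  Mitochondrial load targets a Beta(2, 28) fraction;
5% of cells are planted low-quality (depth ×0.08, mito 60–90%) so QC has a
ground truth.  Real features deliberately **not** emulated: ambient RNA,
doublets, batch effects, UMI collisions, subclonal CNV heterogeneity, and
cell-cycle structure — passing tests therefore demonstrate correctness of
the procedures, not robustness to those artifacts.

**TMA.**  26 patients; H-scores are zero-inflated (30% exact zeros, the
rest uniform over 2–180, rounded to integers as a pathologist would
report); intensity percentages are constructed to sum to 100 while
reproducing each H-score exactly, with mass shuffled between levels at
fixed score.  Recurrence is Bernoulli with a logistic link in the H-score,
slope 0.5 per unit around the planted cutpoint 25 (steep enough that
recovery within one inter-score gap is the expected outcome); survival is
exponential (median 60 months, hazard ×4 for recurrent patients) with
uniform administrative censoring at 24–72 months.

**Peaks.**  Half the peaks are placed inside random gene bodies, half at
random genomic positions; the intragenic / nearest-TSS truth is recorded
by a direct all-pairs scan at generation time.

## Numerical choices and degenerate inputs

Strict inequalities at the nomination gates; p floored at 1e-300 before
log; ES falls back to equal hit weights when all hit scores are zero;
permutation p guarded to 1 (flagged) when no same-sign null draws exist;
IRLS is capped at 50 iterations with a flagged
ratio-of-normalized-means fallback; linear predictors clipped at ±30;
zero-variance genes report correlation 0 (flagged) rather than NaN;
standardization maps zero-variance columns to zero; the ridge solver
switches to the dual form when cells < genes; cutpoint ties resolve to the
smallest candidate; Mann–Whitney enumeration switches to the normal
approximation above `n1*n2 = 100`; the CNV smoother shrinks its window on
short chromosomes and logs it.

## Problem sizes used by the test suite

The bundled checks run the bulk arm at its full design (2,000 genes,
38 samples, 20 seeds), the single-cell arm at 5,000 cells for malignant
calling and 19 patients × 600 cells for association (with 1,000 HVGs — the
7,000-gene setting presumes a transcriptome-scale panel), the TMA arm at
100 replicate cohorts, and the peak utilities at 1,000-element fixtures;
unit tests use smaller toy genomes (400–1,000 genes) where the contract
under test does not depend on scale.

## Known limitations

The DE model has no multi-factor designs, outlier handling or independent
filtering beyond the count floor; dispersion is per-gene method-of-moments,
so its p-values are not numerically comparable to shrinkage-based tools;
phenotype-permutation GSEA is out of scope; the malignancy rule is a
declared automation of a manual step and its thresholds (theta, epithelial
fraction) are dataset-dependent; the cutpoint search reports midpoints,
so reproducing a published cutpoint is subject to within-gap placement;
reference-atlas label transfer, batch integration, doublet detection and
motif analysis are explicitly out of scope.
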