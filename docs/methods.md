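# Methods

This note documents the models and procedures implemented in `atacmod`, the
choices made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## Nucleus quality control

Each ATAC fragment contributes two Tn5 insertions, at its start and at
end − 1 (0-based half-open coordinates throughout). A nucleus passes QC when

- ≥ 1,000 fragments overlap a TSS ± 1 kb window and they make up at least a
  per-sample fraction of all fragments (defaults 7.5%, configurable per
  sample, since library quality differs between preparations);
- the per-bp insertion rate within 25 bp of a TSS (51 bp window) is ≥ 4× the
  rate at 1,900–2,000 bp from a TSS (202 bp over both flanks). Both rates are
  normalized by window width so the ratio is scale-free; a zero far-rate with
  a positive near-rate is capped at 10⁶. The TSS-window count uses fragments
  (any overlap), not insertions.
- the chromosome-deviation score is < 40. The score column-standardizes the
  nuclei × chromosome fragment-proportion matrix (sample SD, ddof = 1) and
  sums |z| over chromosomes; free DNA from broken nuclei distorts these
  proportions. Columns with (numerically) zero SD contribute 0 — a constant
  column carries no contamination signal. The score depends only on
  proportions, never on depth.
- the nucleosome-periodicity score lies between the 1st and 99th within-sample
  percentiles. The score is the summed periodogram power of the
  mean-subtracted 1-bp fragment-size histogram on [1, 1000] bp at periods
  100–300 bp (DFT bins k = 4..10). Support and resolution were chosen so the
  stated band sits inside with margin. Note the raw band power scales with the
  squared histogram mass and is also large for degenerate spike histograms;
  the filter is two-sided precisely so both extremes are removed. Nuclei with
  fewer than 100 fragments get an undefined score and are flagged.

Multiplet (ploidy-class) and doublet calls are consumed as external boolean
columns, not computed: dedicated external tools produce them in real
workflows.
Filters are a pure conjunction and therefore order-independent.

## Embedding and two-pass clustering

The binary site × nucleus matrix is weighted as g·d·f·γ:
g_i = log₂(n / Σ_j f_ij) (IDF) and d_j = 1/Σ_i f_ij², the reciprocal
open-site count (a `document_norm="l2"` switch provides the conventional LSI
1/√Σf² instead; the reciprocal-sum form is the default and is what the tests
pin). Sites are pre-filtered by
IDF-weighted variance g²p(1−p) (> 0.4 for 500-bp tiles, > 0.1 for peaks).

The batch factor γ_ij divides the cohort-wide mean of d·f on site i by the
within-sample mean (pass 1), or restricts both means to the nucleus's coarse
cell type (pass 2). Zero denominators give γ = 1; per nucleus, γ is capped at
Q3²/Q2 of its own values across sites to avoid inflation from small
denominators. Rows are centred and a truncated SVD taken; nuclei live in the
V·D coordinates (30 components computed; 10 retained in pass 1 and 8 in pass
2 by default, matching where singular values bottom out at study scale — all
configurable).

Outliers are removed on the top-2 coordinates by the summed squared distance
to the 5 nearest neighbours, above the 99.5th percentile (the score has no
canonical cutoff; the default removes conservatively and is configurable). Clustering
builds a k = 20 nearest-neighbour graph, weights edges by the Jaccard overlap
of neighbour sets (pruned below 1/15), and optimizes modularity with Leiden
(resolution 1.0 default; low resolutions merge well-separated blobs into
single clusters). Coarse clusters are formed by single-linkage agglomeration
of fine-cluster centroids in the top-2 coordinates within a configurable
fraction (default 0.25) of the global spread, with a manual override map —
this merge is conventionally done by visual inspection, so any automatic
rule is a design choice. Cell types are assigned per cluster by the highest mean
standardized accessibility of known marker genes, with lexicographic
tie-breaking at tolerance 1e-9 and an "ambiguous" label within that
tolerance.

## Bulk deconvolution

Pseudo-bulks u_jk (peaks × cell type × sample) are quantile normalized with a
shared reference distribution (the mean of sorted values over all pseudo-bulk
vectors; ties receive the mean of their assigned reference values). The
nuclei-equivalent b_jk = (Σv/Σu)·a_jk is factorized as b ≈ c_j·d_k by OLS on
log b with type and sample indicators (d₁ = 1). The nuclei-equivalent scalar
of double-ploidy cell types is divided by 2 (generalized to a configurable
divisor): droplet chemistry limits per-nucleus fragment yield in the
single-nucleus assay, while in bulk each nucleus contributes DNA proportional
to its genome copies, so ploidy must be corrected on the bulk side.

Marker peaks: per cell type, peaks are ranked by Welch t (that type's samples
vs all others); over a grid of per-type counts (20–200 by 20) the selected
set minimizing the signature matrix's condition number wins. Identical
profiles leave the condition number unbounded and raise a non-identifiability
error. The signature W is the per-type mean of v on the selected peaks; the
per-peak error variance e² is the mean over types of the across-sample
variance, quartile-capped to [Q1²/Q2, Q3²/Q2] for use as regression weights
(the uncapped copy is retained; all-zero e² falls back to equal weights, and
individual zeros to the smallest positive value).

Platform factors f_i are capped geometric means of y/x ratios over matched
samples, where x = Σ_j a_jk/(Σa)·(1/c_j)·w_j is the pseudo-bulk mixture
scaled to one nucleus. Deconvolution solves F⁻¹y ≈ Wθ by Huber M-estimation
(tuning constant 1.345; bisquare and NNLS options) with rows weighted by
1/e_i, clamps negative θ̂ at zero after fitting (NNLS is provided as a
comparison option, not the default), and rescales c_jθ̂_j onto the simplex.

**Bulk normalization choice.** Forcing mixture bulks onto the pure-type
reference distribution is systematically biased: a mixture's value
distribution is genuinely flatter than any pure type's, so that mapping
distorts the linear mixing relation even in the noise-free limit. Bulk
cohorts of ≥ 2 samples are therefore quantile normalized jointly to their own
mean distribution — same-assay mixtures share a distribution shape, making
the map nearly linear — and the residual systematic bulk-vs-pseudo-bulk
per-peak offset is absorbed by the platform factors. A single bulk sample
falls back to the stored pseudo-bulk reference so one-sample deconvolution
stays well defined.

Condition comparisons regress per-type compositions on condition indicators
(reference condition as baseline) and Bonferroni-correct at
α = 0.05/(n_types × n_non-reference_conditions) — 0.05/21 for 7 types and 3
conditions.

## Activity matrices

Gene scores count insertions in gene body ± 2 kb (window configurable),
unweighted; insertions in overlapping genes count for each. Processing is
fixed-order: median library-size scaling; kNN smoothing of zeros (k = 15
neighbours in 10-component PCA space) floored at 0.001; removal of genes at
the floor in ≥ 1% of nuclei; log₂; quantile normalization across nuclei;
subtraction of the rank-2 SVD approximation (absorbing the dominant sample
batch signal). The imputation is a deliberate simple stand-in for heavier
single-cell imputation models, behind a pluggable step.

Motif deviations: for TF m, expected counts are depth_j × Σ_{i∈m} p_i with
p_i the peak's share of total counts; the raw relative deviation is z-scored
against 50 random background peak sets matched on accessibility deciles (no
GC matching — sequences are not inputs here). TFs matching fewer than 10
peaks are dropped. The z matrix then receives the same quantile normalization
and rank-2 SVD subtraction as the gene scores, in that order. With only a
handful of strong planted factors the leading SVD components coincide with
the factors themselves, so factor-recovery tests read the raw z-scores; at
study scale (hundreds of TFs) the leading components track batch, not a
single factor.

Differential expression uses the continuity- and tie-corrected normal
approximation of the Wilcoxon rank-sum statistic (the choice of statistic is
open; a rank test is robust on imputed scores). The gene-set test scores
a set by the mean over members of w_g|t_g| with a moderated t (pooled
variance shrunk toward the mean with prior df 4) and the multiplicity
down-weight w_g = 1 + √((max_f − f_g)/(max_f − min_f)); the null permutes
sample labels, with the permutation budget max(10,000·scale, 20·n_sets) and
Benjamini–Hochberg FDR across sets. Under a planted alternative, random sets
that happen to contain shifted genes legitimately enrich; type-I calibration
is asserted on global-null data.

## TF-regulation modules

Per gene, a 100-tree regression forest predicts the processed gene score from
all TF deviations plus condition indicator columns, with round(√p) candidate
predictors per split. A predictor's importance is its share of the forest's
total impurity reduction multiplied by the out-of-bag R² (floored at 0), so a
gene's column sums to the proportion of its variance the regulators explain
and pure-noise genes get (near-)zero columns. Condition rows stay in the
matrix for factorization but are excluded from membership reporting and
gene-set universes.

NMF uses the KL-divergence multiplicative updates (Brunet variant), written
in-package so the per-iteration objective is observable (monotonicity is a
tested invariant); 100 random starts by default (NNDSVD start optional),
convergence at relative objective change < 1e-6 or 2,000 iterations. Rank
selection fits a grid (2–10, 20 starts each by default) and picks the rank at
the elbow of the residual curve, operationalized as the maximal centered
second difference r(k−1) − 2r(k) + r(k+1), ties to the smaller rank; a curve
with no positive curvature returns the smallest rank with a warning. On
planted-module data the drops are roughly constant up to the true rank and
collapse after it, which is exactly where the centered second difference
peaks. The residual is the KL fit objective itself.

Module representatives are items ranked in the top 5 by weight AND above half
the module's top weight. Gene-set characterization uses Welch t of member vs
non-member H-weights with a per-module max-statistic (Westfall–Young style)
gene-name permutation: p = (1 + #{max-null ≥ t})/(n_perm + 1), significant
below 0.05 (100 permutations by default, so the smallest attainable p is
1/101).

Split-half consistency recomputes the regulator–regulatee matrix on random
half-splits of the nuclei, approximates each half at the chosen rank, and
correlates the two approximations; the noise floor repeats this five times
with the gene matrix's nucleus labels permuted (TF matrix intact). Because
importances here are scaled by out-of-bag R², fully permuted gene rows yield
all-zero matrices; a degenerate (constant) approximation is assigned
correlation 0 — permuted data shows no consistency by construction, which
makes the floor conservative rather than noisy.

## Gene-set activity and core genes

Member TF rows and gene rows (weight 1 inside the set, 0 outside; a symbol
present as both contributes both rows) are z-standardized, stacked, and the
first right-singular vector is the per-nucleus activity score — the first
principal component of the member rows, which downweights peripheral members
and lets activators and suppressors pull with opposite signs. Zero-variance
rows are excluded with a warning. The sign of a singular vector is
arbitrary; it is fixed so the score correlates positively with the mean
member row.
Significance permutes the TF-weight and gene-weight vectors independently
within their blocks, 100 trials, comparing first singular values; a joint
flag is not provided because the blocks have different row counts and
variances, making within-block permutation the exchangeable null.

Condition effects on the score are summarized by the Mann–Whitney AUROC vs a
reference condition ("*" above 0.75, "**" above 0.9, mirrored below
0.25/0.1 for decreases). Core-gene calls combine |Pearson correlation with
the activity score| ≥ 0.3 (the threshold at which zonation classification
separates pericentral from periportal hepatocyte genes; configurable) with PPI totals to the set (sum of edge
scores to members, self-edges excluded) in the top 5% across scored symbols —
dense ranking, boundary ties included. Core symbols outside the set are
reported as novel candidates.

## Synthetic data

The generators define the test conditions; all are deterministic given
(config, seed) and record the exact labels/parameters used in sampling.

- **Genome**: 21 chromosomes (a rat-like autosome count) of decreasing length
  (3 → 1 Mb), one TSS per 100 kb.
- **Fragments**: per-nucleus Poisson depth (default 2,000); a configurable
  fraction centred within 500 bp of a TSS; sizes from a sub-nucleosomal
  exponential plus Gaussians at 200/400 bp with configurable periodic weight;
  chromosome allocation proportional to length, perturbed for planted
  contaminants by a multiple of the multinomial sampling SD (so "3 SD"
  contamination is calibrated against the null).
- **Binary matrices**: per-type open-probability profiles (private signature
  blocks over a shared baseline), per-sample depth multipliers
  exp(N(0, depth_batch_sd²)) clipped to [0, 1], independent Bernoulli draws.
- **Mixture experiments**: each cell type arranges the *same* log-normal peak
  intensity multiset differently (same assay, same value distribution,
  type-specific usage) — this makes quantile normalization
  distribution-preserving, so the noise-free case admits exact recovery while
  markers still arise from arrangement differences. Pseudo-bulk u is Poisson
  around a_jk × depth × s_ij with a droplet-limited per-nucleus depth;
  proportions are Dirichlet(1); bulk intensities mix s by proportion ×
  ploidy, are distorted by per-peak log-normal platform factors (sigma 0.3 by
  default), and Poisson-sampled at fixed library depth. Cell type 0 is
  flagged double-ploidy. A noise-free flag returns expectations.
- **Regulatory datasets**: per-nucleus module activity factors with
  condition-shifted means; member TF/gene rows are loading × factor +
  N(0, noise_sd²), non-members pure noise; one gene set per module holds 80%
  of the module's genes plus 20% decoys, with matched-size random decoy sets;
  PPI edges score ≈ 0.9 within modules and ≈ 0.05 in the background.
  `generate_importance_matrix` plants the module structure directly in a
  nonnegative regulator–regulatee matrix for factorization tests that do not
  need the forest step.

Noise families (Poisson counts, log-normal multiplicative factors, Gaussian
residuals) are the simplest matching count data and multiplicative
distortion; they are not estimated from real data. The generators do **not**
emulate sequence content, GC composition, doublets beyond a labelled flag,
chromatin co-accessibility structure, or realistic peak-count heavy tails —
so passing tests establish the correctness and calibration of the
procedures, not their field performance on real libraries.

## Problem sizes

The test and validation suites run at desk scale as a deliberate design
choice: 1,000 peaks / 7 cell types / 5 mixtures (deconvolution), 50 TFs ×
300 genes over 20 replicates (rank selection), 12–20 TFs and 50–80 genes
with a few hundred nuclei (forests, split-half, activity scores), and
100-nucleus fragment cohorts (QC). Thresholds and tolerances are stated next
to each procedure above; no threshold is tuned to a particular dataset.

## Known limitations

- The coarse-cluster merge rule replaces a visual-inspection step; its
  default fraction is a heuristic and should be reviewed per dataset.
- The document norm defaults to the reciprocal-sum form; the conventional L2
  variant may be preferable and is one switch away.
- chromVAR-style GC-matched backgrounds are not implemented (no sequences);
  accessibility-decile matching only.
- The split-half noise floor is degenerate (exactly zero) under the
  explained-variance importance scaling; it bounds the consistency statistic
  conservatively.
- Deconvolution assumes the reference cell types span the bulk sample;
  missing types are absorbed into (and bias) the represented ones.
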