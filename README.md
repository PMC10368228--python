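# atacmod

Analysis pipeline for single-nucleus and bulk ATAC-seq studies of tissue at
cell-type resolution, built around the workflow used to dissect fatty-liver
disease in a dietary rat model: per-nucleus quality control, batch-corrected
latent semantic indexing (LSI) and clustering of nuclei, reference-based
deconvolution of bulk ATAC-seq into cell-type proportions, discovery of
transcription-factor (TF) regulation modules, and gene-set activity scoring
with core-gene identification. Every input the pipeline consumes can be
generated synthetically with recorded ground truth, so the whole chain is
testable without any sequencing data.

## What it computes

**Nucleus QC** (`atacmod.qc`). Per-nucleus TSS fragment counts and
insertion-rate enrichment, a chromosome-deviation contamination score (sum of
|column-standardized| per-chromosome fragment proportions; nuclei scoring
≥ 40 are discarded), and a nucleosome-periodicity score (summed periodogram
power of the fragment-size histogram at periods 100–300 bp, filtered at the
1st/99th within-sample percentiles).

**Embedding and clustering** (`atacmod.embedding`). For the binary
site × nucleus matrix *f*, the LSI matrix entry is
*g<sub>i</sub> d<sub>j</sub> f<sub>ij</sub> γ<sub>ij</sub>* with IDF weight
*g<sub>i</sub>* = log₂(*n*/Σ<sub>j</sub> *f<sub>ij</sub>*), document norm
*d<sub>j</sub>* = 1/Σ<sub>i</sub> *f<sub>ij</sub>²*, and a per-sample
(optionally per-cell-type) batch factor γ, capped per nucleus at Q3²/Q2 of
its own values. Rows are centred, a truncated SVD taken, nuclei clustered on
the *V·D* coordinates via a shared-nearest-neighbor graph and Leiden
modularity. The procedure runs twice: sample-level correction → coarse cell
types → cell-type-aware correction → final clusters.

**Deconvolution** (`atacmod.deconvolution`). Pseudo-bulk counts *u* per
(cell type *j*, sample *k*) are quantile normalized to *v*; nuclei
equivalents *b<sub>jk</sub>* = (Σ*v*/Σ*u*)·*a<sub>jk</sub>* are factorized as
*b* ≈ *c<sub>j</sub> d<sub>k</sub>* (log-linear fit, *d*₁ = 1, with the
nuclei-equivalent scalar halved for double-ploidy cell types such as
hepatocytes); marker peaks are selected by Welch *t* statistics minimizing
the signature matrix's condition number; per-peak platform factors
*f<sub>i</sub>* = exp(mean<sub>k</sub> log(*y/x*)) on matched samples,
quartile-capped; each bulk vector is deconvolved by Huber robust regression
with per-peak weights 1/*e<sub>i</sub>*, negative coefficients clamped, and
the composition rescaled as *c θ̂*/Σ*c θ̂*.

**Activity matrices** (`atacmod.activity`). Gene-score counting from Tn5
insertions in gene bodies ± 2 kb and its processing chain (library-size
normalization, kNN zero imputation floored at 0.001, low-expression filter,
log₂, quantile normalization, rank-2 SVD subtraction); TF motif-deviation
z-scores against accessibility-matched background peak sets; Wilcoxon
differential expression; and a weighted sample-permutation gene-set test with
BH FDR.

**TF modules** (`atacmod.grn`). Per-gene random-forest importances (√p
candidate predictors per split, importances scaled by out-of-bag R²) form a
regulator–regulatee matrix; Brunet NMF (KL multiplicative updates, best of
100 random starts) factors it into modules, with the rank chosen at the
residual-error elbow; module gene sets are characterized by Welch *t* with a
max-statistic gene-name permutation FWER.

**Gene-set activity and core genes** (`atacmod.gscore`). The per-nucleus
activity of a gene set is the first right-singular vector of the
standardized, membership-weighted stack of TF and gene rows, with permutation
significance; conditions are compared by AUROC (flags at 0.75 / 0.9); core
genes combine |correlation with the activity score| ≥ 0.3 with
protein–protein interaction totals to the set in the top 5%.

## Worked example

```python
import numpy as np
from atacmod import deconvolution as dc
from atacmod.synthetic import SyntheticConfig, generate_mixture_experiment

cfg = SyntheticConfig(seed=1)                       # 7 cell types, sigma 0.3
u, a, y, truth = generate_mixture_experiment(cfg)   # matched sn + bulk data
ref = dc.build_pipeline_reference(u, a, truth.ploidy_flags)
yn = dc.normalize_bulk_cohort(y, ref)
ref.f = dc.fit_platform_factors(ref, a, yn)
errs = np.array([
    dc.deconvolve(yn[:, k], ref, prenormalized=True).composition
    - truth.mixture_proportions[k]
    for k in range(y.shape[1])
])
print(f"error SD {errs.std():.4f}, mean {errs.mean():+.1e}")
```

This prints

```
error SD 0.0084, mean +6.6e-18
```

the spread and bias of the 35 inferred-minus-true cell-type proportions
(7 types × 5 mixtures): compositions are recovered with an SD of about 0.01
and exactly zero mean (both vectors live on the simplex, so per-sample errors
sum to zero).

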