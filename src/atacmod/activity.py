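"""Per-nucleus gene expression scores and TF motif-deviation z-scores, plus
differential expression and sample-permutation gene-set tests on them.

Gene expression is proxied by Tn5 insertion counts in the gene body and
vicinity; the processing chain is library-size normalization, kNN zero
imputation with a 0.001 floor, a low-expression filter, log2, quantile
normalization across nuclei, and subtraction of the first two SVD components
(which absorb the sample batch effect). TF binding is proxied by a deviation
z-score of accessibility at motif-matched peaks against accessibility-matched
background peak sets, post-processed the same way.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import ConfigurationError, FragmentSet, GeneSet, ValidationError
from .deconvolution import quantile_normalize

IMPUTATION_FLOOR = 0.001


# ---------------------------------------------------------------------------
# Gene scores
# ---------------------------------------------------------------------------

def gene_score_counts(
    frags: FragmentSet, genes: pd.DataFrame, window: int = 2000
) -> pd.DataFrame:
    """Count Tn5 insertions (both fragment ends) within gene body +/- window.

    ``genes`` needs columns gene, chrom, start, end (0-based half-open body).
    Insertions in overlapping genes count for every overlapping gene.
    """
    ins = frags.insertion_positions()
    barcodes = list(frags.barcodes)
    bc_idx = {b: i for i, b in enumerate(barcodes)}
    out = np.zeros((len(genes), len(barcodes)), dtype=float)
    pos = ins["pos"].to_numpy()
    col = ins["barcode"].map(bc_idx).to_numpy()
    by_chrom = ins.groupby("chrom").indices
    for r, gene in enumerate(genes.itertuples(index=False)):
        idx = by_chrom.get(gene.chrom)
        if idx is None:
            continue
        p = pos[idx]
        hit = (p >= gene.start - window) & (p < gene.end + window)
        if hit.any():
            np.add.at(out[r], col[idx[hit]], 1.0)
    return pd.DataFrame(out, index=genes["gene"].tolist(), columns=barcodes)


def _knn_impute_zeros(X: np.ndarray, k: int = 15, n_pcs: int = 10) -> np.ndarray:
    """Replace zero entries by the mean over each nucleus's k nearest
    neighbours (in PCA space over nuclei), then floor at 0.001."""
    n = X.shape[1]
    k = min(k, n - 1)
    pcs = PCA(n_components=min(n_pcs, min(X.shape) - 1), random_state=0)
    coords = pcs.fit_transform(np.log1p(X).T)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    out = X.copy()
    for j in range(n):
        zeros = np.flatnonzero(X[:, j] == 0)
        if len(zeros) == 0:
            continue
        neigh = idx[j, 1:]
        out[zeros, j] = X[np.ix_(zeros, neigh)].mean(axis=1)
    return np.maximum(out, IMPUTATION_FLOOR)


def subtract_svd_components(X: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Subtract the leading rank-``n_components`` SVD approximation."""
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    return X - (U[:, :n_components] * s[:n_components]) @ Vt[:n_components]


def process_gene_scores(
    raw: pd.DataFrame,
    *,
    impute_k: int = 15,
    low_expression_fraction: float = 0.01,
) -> pd.DataFrame:
    """Fixed-order processing of the raw gene score matrix (genes x nuclei):
    (1) scale nuclei to the median library size, (2) kNN zero imputation with
    floor 0.001, (3) drop genes at the floor in >= 1% of nuclei, (4) log2,
    (5) quantile normalization across nuclei, (6) subtract the first two SVD
    components."""
    X = raw.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    empty = lib == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} empty nuclei")
        X = X[:, ~empty]
        lib = lib[~empty]
    cols = raw.columns[~empty] if empty.any() else raw.columns
    X = X * (np.median(lib) / lib)[None, :]
    X = _knn_impute_zeros(X, k=impute_k)
    at_floor = (X <= IMPUTATION_FLOOR).mean(axis=1)
    keep = at_floor < low_expression_fraction
    X = X[keep]
    X = np.log2(X)
    X, _ = quantile_normalize(X)
    X = subtract_svd_components(X, 2)
    return pd.DataFrame(X, index=raw.index[keep], columns=cols)


# ---------------------------------------------------------------------------
# Motif deviation z-scores
# ---------------------------------------------------------------------------

def motif_deviation_zscores(
    peak_matrix: np.ndarray,
    motif_matches: pd.DataFrame,
    *,
    n_background: int = 50,
    min_peaks: int = 10,
    seed: int = 0,
    postprocess: bool = True,
) -> pd.DataFrame:
    """Per-nucleus TF-binding deviation z-scores.

    ``peak_matrix`` is peaks x nuclei (binary or counts); ``motif_matches`` is
    a binary peaks x TFs table. For TF m, the expected count in nucleus j is
    depth_j * sum_{i in m} p_i with p_i the peak's share of total counts; the
    raw deviation (obs - exp)/exp is z-scored against ``n_background`` random
    peak sets matched on accessibility deciles. TFs with fewer than
    ``min_peaks`` matched peaks are dropped. When ``postprocess`` is set the
    z matrix is quantile normalized and its first two SVD components removed.
    """
    X = np.asarray(peak_matrix, dtype=float)
    P, n = X.shape
    rng = np.random.default_rng(seed)
    totals = X.sum()
    p_i = X.sum(axis=1) / totals
    depth = X.sum(axis=0)

    deciles = np.minimum((np.argsort(np.argsort(p_i)) * 10) // P, 9)
    pools = [np.flatnonzero(deciles == d) for d in range(10)]

    def _deviation(peaks_idx: np.ndarray) -> np.ndarray:
        obs = X[peaks_idx].sum(axis=0)
        exp = depth * p_i[peaks_idx].sum()
        exp = np.where(exp > 0, exp, 1.0)
        return (obs - exp) / exp

    rows, names = [], []
    for tf in motif_matches.columns:
        peaks_idx = np.flatnonzero(motif_matches[tf].to_numpy())
        if len(peaks_idx) < min_peaks:
            warnings.warn(f"TF {tf} has <{min_peaks} matched peaks; dropped")
            continue
        raw = _deviation(peaks_idx)
        counts = np.bincount(deciles[peaks_idx], minlength=10)
        bg = np.empty((n_background, n))
        for b in range(n_background):
            sel = np.concatenate([
                rng.choice(pools[dec], size=c, replace=c > len(pools[dec]))
                for dec, c in enumerate(counts) if c > 0
            ])
            bg[b] = _deviation(sel)
        mu, sd = bg.mean(axis=0), bg.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        rows.append((raw - mu) / sd)
        names.append(tf)
    Z = np.vstack(rows)
    if postprocess:
        Z, _ = quantile_normalize(Z)
        Z = subtract_svd_components(Z, 2)
    cols = (peak_matrix.columns if isinstance(peak_matrix, pd.DataFrame)
            else range(n))
    return pd.DataFrame(Z, index=names, columns=cols)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def rank_sum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Continuity- and tie-corrected normal approximation of the Wilcoxon
    rank-sum statistic; positive when x stochastically exceeds y."""
    nx, ny = len(x), len(y)
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    W = ranks[:nx].sum()
    mu = nx * (ny + nx + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    n = nx + ny
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = nx * ny / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0
    diff = W - mu
    correction = -0.5 if diff > 0 else (0.5 if diff < 0 else 0.0)
    return float((diff + correction) / np.sqrt(var))


def dge_zscores(
    matrix: pd.DataFrame,
    conditions: np.ndarray,
    reference_condition: str,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum z comparing each condition against the
    reference; constant genes get z = 0."""
    conditions = np.asarray(conditions)
    ref_mask = conditions == reference_condition
    if ref_mask.sum() < 2:
        raise ConfigurationError("reference condition needs >= 2 nuclei")
    X = matrix.to_numpy(dtype=float)
    out = {}
    for cond in pd.unique(conditions):
        if cond == reference_condition:
            continue
        mask = conditions == cond
        if mask.sum() < 2:
            raise ConfigurationError(f"condition {cond} needs >= 2 nuclei")
        z = np.array([
            0.0 if (row[mask].std() == 0 and row[ref_mask].std() == 0
                    and row[mask].mean() == row[ref_mask].mean())
            else rank_sum_z(row[mask], row[ref_mask])
            for row in X
        ])
        out[cond] = z
    return pd.DataFrame(out, index=matrix.index)


# ---------------------------------------------------------------------------
# Sample-permutation gene-set enrichment
# ---------------------------------------------------------------------------

def _moderated_t(X: np.ndarray, mask_a: np.ndarray, mask_b: np.ndarray,
                 prior_df: float = 4.0) -> np.ndarray:
    """Two-sample t with pooled-variance shrinkage towards the mean variance
    (prior degrees of freedom ``prior_df``)."""
    a, b = X[:, mask_a], X[:, mask_b]
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    s0 = sp2.mean()
    s2 = (prior_df * s0 + df * sp2) / (prior_df + df)
    se = np.sqrt(s2 * (1 / na + 1 / nb))
    se = np.where(se > 0, se, np.inf)
    return (a.mean(axis=1) - b.mean(axis=1)) / se


def permutation_count(n_sets: int, scale: float = 1.0) -> int:
    """max(10,000 * scale, 20 * n_sets): the permutation budget rule."""
    return int(max(round(10_000 * scale), 20 * n_sets))


def gs_enrichment_sample_perm(
    matrix: pd.DataFrame,
    labels: np.ndarray,
    gene_sets: list[GeneSet],
    n_perm: int | None = None,
    *,
    scale: float = 1.0,
    prior_df: float = 4.0,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Sample-permutation gene-set enrichment between two groups.

    Per gene, a moderated |t|; genes appearing in many sets are down-weighted
    by w_g = 1 + sqrt((max_f - f_g)/(max_f - min_f)) with f_g the number of
    sets containing g; a set's score is the mean of w_g |t_g| over members.
    The null permutes the group labels; p = (1 + #null >= obs)/(n_perm + 1),
    Benjamini-Hochberg FDR across sets.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ConfigurationError("exactly two groups required")
    mask_a = labels == groups[0]
    mask_b = labels == groups[1]
    X = matrix.to_numpy(dtype=float)
    genes = pd.Index(matrix.index)

    member_idx = {}
    for gs in gene_sets:
        idx = genes.get_indexer([g for g in gs.members if g in genes])
        idx = idx[idx >= 0]
        if len(idx) == 0:
            warnings.warn(f"gene set {gs.name} has no genes in the matrix; skipped")
            continue
        member_idx[gs.name] = idx
    if not member_idx:
        raise ValidationError("no testable gene sets")
    if n_perm is None:
        n_perm = permutation_count(len(member_idx), scale)

    f_g = np.zeros(len(genes))
    for idx in member_idx.values():
        f_g[idx] += 1
    fmax, fmin = f_g.max(), f_g.min()
    if fmax > fmin:
        w_g = 1 + np.sqrt((fmax - f_g) / (fmax - fmin))
    else:
        w_g = np.ones_like(f_g)

    def _scores(ma, mb):
        t = np.abs(_moderated_t(X, ma, mb, prior_df))
        wt = w_g * t
        return {name: wt[idx].mean() for name, idx in member_idx.items()}

    observed = _scores(mask_a, mask_b)
    rng = np.random.default_rng(seed)
    exceed = {name: 0 for name in member_idx}
    n = len(labels)
    na = int(mask_a.sum())
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pa = np.zeros(n, dtype=bool)
        pa[perm[:na]] = True
        null = _scores(pa, ~pa)
        for name in member_idx:
            if null[name] >= observed[name]:
                exceed[name] += 1
    names = list(member_idx)
    p = np.array([(1 + exceed[name]) / (n_perm + 1) for name in names])
    _, fdr, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "set": names,
        "score": [observed[n_] for n_ in names],
        "p": p,
        "fdr": fdr,
        "significant": fdr < fdr_alpha,
    }).set_index("set")
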