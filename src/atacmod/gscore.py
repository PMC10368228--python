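"""Gene-set (GS) activity scores in single nuclei and core-gene discovery.

The GS activity score is the first right-singular vector of the standardized,
set-restricted stack of TF-deviation and gene-score rows — a per-nucleus
pathway activity proxy that, unlike a plain member average, downweights
peripheral members and lets activators and suppressors pull in opposite
directions. Significance comes from permuting the 0/1 membership weights
within the TF and gene blocks. Core genes combine a strong correlation with
the activity score and protein-protein interaction totals to the set within
the top 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .io import GeneSet, PPINetwork, ValidationError


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = sd[:, 0] > 0
    Z = np.zeros_like(X)
    Z[ok] = (X[ok] - mu[ok]) / sd[ok]
    return Z, ok


@dataclass
class GSActivityResult:
    score: np.ndarray  # per nucleus, unit norm
    first_singular_value: float
    orientation: int
    members_tf: list[str] = field(default_factory=list)
    members_gene: list[str] = field(default_factory=list)
    p_value: float | None = None


def _weighted_stack(
    gene_matrix: pd.DataFrame,
    tf_matrix: pd.DataFrame,
    tf_weights: np.ndarray,
    gene_weights: np.ndarray,
) -> np.ndarray:
    Ztf, ok_tf = _standardize_rows(tf_matrix.to_numpy(dtype=float))
    Zg, ok_g = _standardize_rows(gene_matrix.to_numpy(dtype=float))
    if not ok_tf.all() or not ok_g.all():
        warnings.warn("zero-variance rows excluded from the GS stack")
    return np.vstack([Ztf * (tf_weights * ok_tf)[:, None],
                      Zg * (gene_weights * ok_g)[:, None]])


def gs_activity_score(
    gene_matrix: pd.DataFrame,
    tf_matrix: pd.DataFrame,
    gene_set: GeneSet,
) -> GSActivityResult:
    """First right-singular vector of the standardized member-row stack.

    A symbol appearing both as a TF row and a gene row contributes both rows.
    The sign is fixed so the score correlates positively with the mean of the
    weighted standardized member rows.
    """
    tf_w = np.array([1.0 if t in gene_set.members else 0.0 for t in tf_matrix.index])
    gene_w = np.array([1.0 if g in gene_set.members else 0.0 for g in gene_matrix.index])
    members_tf = [t for t in tf_matrix.index if t in gene_set.members]
    members_gene = [g for g in gene_matrix.index if g in gene_set.members]
    if len(members_tf) + len(members_gene) < 2:
        raise ValidationError(
            f"gene set {gene_set.name!r}: fewer than 2 members present")
    stack = _weighted_stack(gene_matrix, tf_matrix, tf_w, gene_w)
    nonzero = np.abs(stack).sum(axis=1) > 0
    sub = stack[nonzero]
    if sub.shape[0] < 2:
        raise ValidationError("fewer than 2 usable member rows")
    U, s, Vt = scipy.linalg.svd(sub, full_matrices=False)
    score = Vt[0]
    member_mean = sub.mean(axis=0)
    sign = 1 if np.dot(score, member_mean) >= 0 else -1
    return GSActivityResult(
        score=sign * score,
        first_singular_value=float(s[0]),
        orientation=sign,
        members_tf=members_tf,
        members_gene=members_gene,
    )


def gs_activity_significance(
    gene_matrix: pd.DataFrame,
    tf_matrix: pd.DataFrame,
    gene_set: GeneSet,
    *,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> GSActivityResult:
    """Permutation P-value for the GS activity score: the 0/1 TF weights and
    gene weights are permuted independently within their blocks and the first
    singular value recomputed; p = (1 + #null >= obs)/(n_perm + 1). Sets with
    p >= ``alpha`` are not meaningfully co-expressed."""
    result = gs_activity_score(gene_matrix, tf_matrix, gene_set)
    tf_w = np.array([1.0 if t in gene_set.members else 0.0 for t in tf_matrix.index])
    gene_w = np.array([1.0 if g in gene_set.members else 0.0 for g in gene_matrix.index])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        stack = _weighted_stack(gene_matrix, tf_matrix,
                                rng.permutation(tf_w), rng.permutation(gene_w))
        sub = stack[np.abs(stack).sum(axis=1) > 0]
        s1 = scipy.linalg.svd(sub, compute_uv=False)[0] if len(sub) else 0.0
        if s1 >= result.first_singular_value:
            exceed += 1
    result.p_value = (1 + exceed) / (n_perm + 1)
    return result


def condition_auroc(
    score: np.ndarray,
    conditions: np.ndarray,
    reference_condition: str,
) -> pd.DataFrame:
    """Mann-Whitney AUROC of the activity score per condition vs the
    reference; '*' above 0.75, '**' above 0.9 (and analogously below 0.25 /
    0.1 for decreases)."""
    score = np.asarray(score, dtype=float)
    conditions = np.asarray(conditions)
    ref = score[conditions == reference_condition]
    if len(ref) < 2:
        raise ValidationError("reference condition needs >= 2 nuclei")
    rows = []
    for cond in pd.unique(conditions):
        if cond == reference_condition:
            continue
        grp = score[conditions == cond]
        if len(grp) < 2:
            warnings.warn(f"condition {cond} has <2 nuclei; skipped")
            continue
        u = scipy.stats.mannwhitneyu(grp, ref, alternative="two-sided").statistic
        auroc = float(u / (len(grp) * len(ref)))
        if auroc > 0.9 or auroc < 0.1:
            flag = "**"
        elif auroc > 0.75 or auroc < 0.25:
            flag = "*"
        else:
            flag = ""
        rows.append((cond, auroc, flag, "up" if auroc > 0.5 else "down"))
    return pd.DataFrame(rows, columns=["condition", "auroc", "flag", "direction"])


def ppi_totals(
    symbols: list[str], gene_set: GeneSet, ppi: PPINetwork
) -> pd.Series:
    """Sum of PPI edge scores between each symbol and the GS members,
    excluding self-edges; absent symbols get 0."""
    edges = ppi.edges
    members = gene_set.members
    totals = dict.fromkeys(symbols, 0.0)
    for n1, n2, score in edges[["node1", "node2", "score"]].itertuples(index=False):
        if n1 == n2:
            continue
        if n1 in totals and n2 in members:
            totals[n1] += score
        if n2 in totals and n1 in members:
            totals[n2] += score
    return pd.Series(totals, name="ppi_total")


def core_gene_table(
    correlations: pd.Series,
    ppi_total: pd.Series,
    gene_set: GeneSet,
    kinds: pd.Series | None = None,
    *,
    top_ppi_fraction: float = 0.05,
    corr_threshold: float = 0.3,
) -> pd.DataFrame:
    """Core-gene calls: PPI total within the top 5% across all scored symbols
    (dense ranking; boundary ties included) AND |correlation with the activity
    score| >= threshold. Symbols in and out of the GS are flagged; novel
    candidates are core symbols outside the GS."""
    symbols = correlations.index
    ppi_total = ppi_total.reindex(symbols).fillna(0.0)
    n_top = max(1, int(np.ceil(top_ppi_fraction * len(symbols))))
    boundary = np.sort(ppi_total.to_numpy())[::-1][n_top - 1]
    top_flag = ppi_total >= boundary
    core = top_flag & (correlations.abs() >= corr_threshold)
    table = pd.DataFrame({
        "kind": kinds.reindex(symbols) if kinds is not None else "gene",
        "correlation": correlations,
        "ppi_total": ppi_total,
        "in_gs": [s in gene_set.members for s in symbols],
        "top_ppi": top_flag,
        "core": core,
    })
    table["novel_candidate"] = table["core"] & ~table["in_gs"]
    return table


def activity_correlations(
    result: GSActivityResult,
    gene_matrix: pd.DataFrame,
    tf_matrix: pd.DataFrame,
) -> tuple[pd.Series, pd.Series]:
    """Pearson correlation of every TF and gene row with the activity score,
    plus a kind series ('tf'/'gene'). Zero-variance rows get correlation 0."""
    s = result.score - result.score.mean()
    zs = s / s.std() if s.std() > 0 else s

    def _corr(matrix):
        X = matrix.to_numpy(dtype=float)
        Z, ok = _standardize_rows(X)  # rows are z-scores
        vals = (Z * zs[None, :]).mean(axis=1)
        vals[~ok] = 0.0
        return pd.Series(vals, index=matrix.index)

    tf_corr = _corr(tf_matrix)
    gene_corr = _corr(gene_matrix)
    corr = pd.concat([tf_corr, gene_corr])
    kinds = pd.Series(["tf"] * len(tf_corr) + ["gene"] * len(gene_corr),
                      index=corr.index)
    return corr, kinds
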