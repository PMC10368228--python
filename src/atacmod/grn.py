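"""TF-regulation module discovery: per-gene random-forest importances,
nonnegative matrix factorization of the regulator-regulatee matrix, rank
selection by the residual-error elbow, and permutation-FWER gene-set
enrichment of module gene weights.

The regulator-regulatee matrix R has one row per regulator (TF deviation rows
plus condition indicators) and one column per gene; an entry is the proportion
of the gene's variance explained by that regulator (per-predictor impurity
reduction apportioning the forest's out-of-bag R^2). NMF uses the
KL-divergence multiplicative updates (the Brunet variant), run from many
random starts and keeping the lowest objective; the updates are written here
so the per-iteration objective is observable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestRegressor

from .io import ConfigurationError, GeneSet, ValidationError

_EPS = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# Regulator-regulatee matrix
# ---------------------------------------------------------------------------

def default_k(n_predictors: int) -> int:
    """Default number of candidate regulators per split: round(sqrt(p))."""
    return max(1, int(round(np.sqrt(n_predictors))))


def regulator_importances(
    gene_matrix: pd.DataFrame,
    tf_matrix: pd.DataFrame,
    conditions: np.ndarray | None = None,
    *,
    n_trees: int = 100,
    K: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Nonnegative importance of each regulator for each gene.

    Per gene, a regression forest predicts the gene's expression score from
    all TF deviations plus condition indicators; K (``max_features``) defaults
    to round(sqrt(#predictors)). A predictor's importance is its share of the
    forest's impurity reduction scaled by the out-of-bag R^2 (floored at 0),
    so per-gene column sums equal the explained-variance proportion.
    Zero-variance genes get zero columns.
    """
    if list(gene_matrix.columns) != list(tf_matrix.columns):
        raise ValidationError("gene and TF matrices must share nuclei")
    predictors = tf_matrix.to_numpy(dtype=float).T  # nuclei x TFs
    names = list(tf_matrix.index)
    if conditions is not None:
        conditions = np.asarray(conditions)
        levels = list(pd.unique(conditions))
        indicators = np.column_stack([(conditions == c).astype(float) for c in levels])
        predictors = np.hstack([predictors, indicators])
        names = names + [f"condition:{c}" for c in levels]
    p = predictors.shape[1]
    if K is None:
        K = default_k(p)
    K = max(1, min(K, p))
    rng = np.random.default_rng(seed)
    R = np.zeros((p, gene_matrix.shape[0]))
    for g, (_, row) in enumerate(gene_matrix.iterrows()):
        y = row.to_numpy(dtype=float)
        if y.std() == 0:
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=K,
            oob_score=True,
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            forest.fit(predictors, y)
        r2 = max(0.0, float(forest.oob_score_))
        R[:, g] = forest.feature_importances_ * r2
    kind = ["tf"] * len(tf_matrix.index) + ["condition"] * (p - len(tf_matrix.index))
    out = pd.DataFrame(R, index=names, columns=gene_matrix.index)
    out.attrs["row_kind"] = kind
    return out


# ---------------------------------------------------------------------------
# Brunet NMF (KL multiplicative updates)
# ---------------------------------------------------------------------------

def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH), the Brunet objective."""
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    return float((V[mask] * np.log(V[mask] / WH[mask])).sum() - V.sum() + WH.sum())


def _nndsvd_init(V: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Nonnegative double SVD initialization."""
    U, s, Vt = np.linalg.svd(V, full_matrices=False)
    W = np.zeros((V.shape[0], rank))
    H = np.zeros((rank, V.shape[1]))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    H[0] = np.sqrt(s[0]) * np.abs(Vt[0])
    for r in range(1, rank):
        u, v = U[:, r], Vt[r]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        term_p = np.linalg.norm(up) * np.linalg.norm(vp)
        term_n = np.linalg.norm(un) * np.linalg.norm(vn)
        if term_p >= term_n:
            W[:, r] = np.sqrt(s[r] * term_p) * up / max(np.linalg.norm(up), _EPS)
            H[r] = np.sqrt(s[r] * term_p) * vp / max(np.linalg.norm(vp), _EPS)
        else:
            W[:, r] = np.sqrt(s[r] * term_n) * un / max(np.linalg.norm(un), _EPS)
            H[r] = np.sqrt(s[r] * term_n) * vn / max(np.linalg.norm(vn), _EPS)
    mean = V.mean()
    W[W == 0] = mean / rank
    H[H == 0] = mean / rank
    return W, H


def _kl_updates(V, W, H, max_iter, tol):
    history = []
    obj = kl_divergence(V, W @ H)
    history.append(obj)
    for _ in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        new_obj = kl_divergence(V, W @ H)
        history.append(new_obj)
        if obj - new_obj < tol * max(abs(obj), 1.0):
            break
        obj = new_obj
    return W, H, history


@dataclass
class ModuleDecomposition:
    W: np.ndarray  # regulators x rank
    H: np.ndarray  # rank x genes
    rank: int
    objective: float
    history: list[float] = field(default_factory=list)
    seed: int = 0
    regulators: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


def nmf_brunet(
    R: pd.DataFrame | np.ndarray,
    rank: int,
    *,
    n_starts: int = 100,
    nndsvd_start: bool = False,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> ModuleDecomposition:
    """KL-divergence multiplicative-update NMF; best of ``n_starts`` random
    nonnegative initializations (plus an optional NNDSVD start)."""
    V = np.asarray(R, dtype=float)
    if (V < 0).any():
        raise ValidationError("NMF input must be nonnegative")
    if rank < 1 or rank > min(V.shape):
        raise ValidationError(f"rank must lie in [1, {min(V.shape)}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(V.mean() / rank)
    best = None
    starts = [("random", i) for i in range(n_starts)]
    if nndsvd_start:
        starts.append(("nndsvd", -1))
    for kind, _ in starts:
        if kind == "nndsvd":
            W0, H0 = _nndsvd_init(V, rank)
        else:
            W0 = rng.random((V.shape[0], rank)) * 2 * scale
            H0 = rng.random((rank, V.shape[1])) * 2 * scale
        W, H, history = _kl_updates(V, W0, H0, max_iter, tol)
        if best is None or history[-1] < best.objective:
            best = ModuleDecomposition(W, H, rank, history[-1], history, seed)
    if isinstance(R, pd.DataFrame):
        best.regulators = list(R.index)
        best.genes = list(R.columns)
    return best


def select_rank(
    R: pd.DataFrame | np.ndarray,
    rank_grid: tuple[int, ...] = tuple(range(2, 11)),
    *,
    n_starts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[int, np.ndarray]:
    """Choose the NMF rank at the residual-error elbow.

    Fits each rank in the grid (reduced random starts) and picks the rank
    maximizing the centered second difference of the residual curve (ties go
    to the smaller rank); a curve with no positive curvature returns the
    smallest rank with a warning.
    """
    rank_grid = tuple(rank_grid)
    if len(rank_grid) < 4:
        raise ConfigurationError("rank grid needs >= 4 consecutive ranks")
    residuals = np.array([
        nmf_brunet(R, r, n_starts=n_starts, max_iter=max_iter, tol=tol,
                   seed=seed + 1000 * r).objective
        for r in rank_grid
    ])
    chosen = elbow_rank(rank_grid, residuals)
    return chosen, residuals


def elbow_rank(rank_grid: tuple[int, ...], residuals: np.ndarray) -> int:
    """Rank at the maximal centered second difference
    r(k-1) - 2 r(k) + r(k+1) of the residual curve."""
    d2 = residuals[:-2] - 2 * residuals[1:-1] + residuals[2:]
    if d2.max() <= 0:
        warnings.warn("residual curve has no elbow; returning smallest rank")
        return rank_grid[0]
    return rank_grid[1 + int(np.argmax(d2))]


# ---------------------------------------------------------------------------
# Module reporting and enrichment
# ---------------------------------------------------------------------------

def module_membership(
    weights: np.ndarray, names: list[str], top_n: int = 5, frac_of_top: float = 0.5
) -> list[list[str]]:
    """Representatives per module: ranked in the top ``top_n`` by weight AND
    weighing more than ``frac_of_top`` of the module's top weight."""
    weights = np.asarray(weights)  # items x modules
    out = []
    for m in range(weights.shape[1]):
        w = weights[:, m]
        order = np.argsort(-w, kind="stable")
        top = w[order[0]]
        reps = [names[i] for i in order[:top_n] if w[i] > frac_of_top * top]
        out.append(reps)
    return out


def assign_to_modules(W: np.ndarray) -> np.ndarray:
    """Hard module assignment of regulators: argmax of the W row."""
    return np.argmax(np.asarray(W), axis=1)


def module_gs_enrichment(
    H: np.ndarray,
    gene_names: list[str],
    gene_sets: list[GeneSet],
    *,
    n_perm: int = 100,
    min_overlap: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t of member vs non-member gene weights per (module, set), with a
    max-statistic gene-name permutation FWER per module."""
    H = np.asarray(H)
    genes = pd.Index(gene_names)
    sets = {}
    for gs in gene_sets:
        mask = genes.isin(gs.members)
        if mask.sum() < min_overlap:
            continue
        sets[gs.name] = mask
    if not sets:
        raise ValidationError("no gene set overlaps the universe enough")
    rng = np.random.default_rng(seed)

    def _t(weights, mask):
        a, b = weights[mask], weights[~mask]
        if len(a) < 2 or len(b) < 2:
            return 0.0
        return float(scipy.stats.ttest_ind(a, b, equal_var=False).statistic)

    rows = []
    for m in range(H.shape[0]):
        w = H[m]
        observed = {name: _t(w, mask) for name, mask in sets.items()}
        max_null = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(len(w))
            wp = w[perm]
            max_null[b] = max(_t(wp, mask) for mask in sets.values())
        for name, t in observed.items():
            p = (1 + int((max_null >= t).sum())) / (n_perm + 1)
            rows.append((m, name, t, p, p < alpha))
    return pd.DataFrame(rows, columns=["module", "set", "t", "fwer_p", "significant"])


# ---------------------------------------------------------------------------
# Split-half consistency
# ---------------------------------------------------------------------------

def split_half_consistency(
    gene_matrix: pd.DataFrame,
    tf_matrix: pd.DataFrame,
    conditions: np.ndarray | None,
    *,
    rank: int,
    n_trees: int = 50,
    K: int | None = None,
    n_starts: int = 10,
    n_permutations: int = 5,
    max_iter: int = 500,
    seed: int = 0,
) -> dict:
    """Consistency of module discovery across a random half-split of nuclei.

    The regulator-regulatee matrix is computed in each half, approximated by
    rank-``rank`` NMF, and the two approximations correlated (Pearson over
    entries). The noise floor repeats this with the gene matrix's nucleus
    labels permuted (TF matrix intact), ``n_permutations`` times.
    """
    rng = np.random.default_rng(seed)
    n = gene_matrix.shape[1]
    if n < 200:
        raise ConfigurationError("need >= 200 nuclei for a stable split")

    def _approx(gm, tm, cond, s):
        R = regulator_importances(gm, tm, cond, n_trees=n_trees, K=K, seed=s)
        dec = nmf_brunet(R, rank, n_starts=n_starts, max_iter=max_iter, seed=s)
        return dec.W @ dec.H

    def _split_corr(gm, s):
        perm = rng.permutation(n)
        halves = perm[: n // 2], perm[n // 2 : 2 * (n // 2)]
        approx = []
        for h, idx in enumerate(halves):
            cond = conditions[idx] if conditions is not None else None
            approx.append(_approx(gm.iloc[:, idx], tf_matrix.iloc[:, idx], cond,
                                  s + h))
        a, b = approx[0].ravel(), approx[1].ravel()
        if a.std() == 0 or b.std() == 0:
            return 0.0  # a degenerate (all-zero) half shows no consistency
        return float(np.corrcoef(a, b)[0, 1])

    observed = _split_corr(gene_matrix, seed)
    floor = []
    for t in range(n_permutations):
        shuffled = gene_matrix.iloc[:, rng.permutation(n)]
        shuffled.columns = gene_matrix.columns
        floor.append(_split_corr(shuffled, seed + 100 + t))
    floor = np.asarray(floor)
    return {
        "correlation": observed,
        "floor_trials": floor,
        "floor_mean": float(floor.mean()),
        "floor_sd": float(floor.std(ddof=1)),
    }
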