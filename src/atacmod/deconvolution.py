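"""Reference-based deconvolution of bulk ATAC-seq using snATAC pseudo-bulks.

The pipeline follows the bookkeeping of matched single-nucleus / bulk
experiments: pseudo-bulk counts u per (cell type j, sample k) are quantile
normalized to v; the nuclei-equivalent b_jk = (sum v / sum u) a_jk is
factorized as b ~ c_j d_k (log-linear least squares, d_1 = 1, with a ploidy
divisor for flagged cell types); marker peaks are chosen by Welch t statistics
while minimizing the signature matrix's condition number; per-peak platform
factors f are the capped geometric means of bulk/pseudo-mixture ratios on
matched samples; and each bulk vector is deconvolved by Huber robust
regression weighted by capped per-peak error variances, with negative
coefficients clamped to zero and the composition rescaled onto the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .io import ConfigurationError, ValidationError


# ---------------------------------------------------------------------------
# Pseudo-bulk and quantile normalization
# ---------------------------------------------------------------------------

def pseudo_bulk(
    counts: np.ndarray, cell_types: np.ndarray, samples: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list, list]:
    """Sum per-nucleus peak counts within (cell type, sample) groups.

    Returns (u, a, type_names, sample_names) with u of shape
    (peaks, types, samples) and a the group nucleus counts; empty groups hold
    zeros in u and 0 in a (and are skipped downstream with a warning).
    """
    counts = np.asarray(counts, dtype=float)
    cell_types = np.asarray(cell_types)
    samples = np.asarray(samples)
    type_names = sorted(np.unique(cell_types).tolist())
    sample_names = sorted(np.unique(samples).tolist())
    P = counts.shape[0]
    u = np.zeros((P, len(type_names), len(sample_names)))
    a = np.zeros((len(type_names), len(sample_names)))
    for j, t in enumerate(type_names):
        for k, s in enumerate(sample_names):
            mask = (cell_types == t) & (samples == s)
            if not mask.any():
                warnings.warn(f"empty pseudo-bulk group ({t}, {s}); omitted")
                continue
            u[:, j, k] = counts[:, mask].sum(axis=1)
            a[j, k] = mask.sum()
    return u, a, type_names, sample_names


def quantile_reference(vectors: np.ndarray) -> np.ndarray:
    """Mean of sorted values across columns: the shared target distribution."""
    return np.sort(np.asarray(vectors, dtype=float), axis=0).mean(axis=1)


def quantile_normalize(
    vectors: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile normalize each column to the reference distribution
    (computed from the input when not given); tied values receive the mean of
    their assigned reference values."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if reference is None:
        reference = quantile_reference(X)
    reference = np.asarray(reference, dtype=float)
    if len(reference) != X.shape[0]:
        raise ValidationError("vector length does not match stored reference")
    ref_sorted = np.sort(reference)
    out = np.empty_like(X)
    for c in range(X.shape[1]):
        x = X[:, c]
        order = np.argsort(x, kind="stable")
        assigned = np.empty_like(x)
        assigned[order] = ref_sorted
        # average assigned values within tie groups
        uniq, inv = np.unique(x, return_inverse=True)
        sums = np.bincount(inv, weights=assigned)
        cnts = np.bincount(inv)
        out[:, c] = (sums / cnts)[inv]
    return out, reference


def nuclei_equivalents(u: np.ndarray, v: np.ndarray, a: np.ndarray) -> np.ndarray:
    """b_jk = (sum_i v_ijk / sum_i u_ijk) * a_jk; zero-total groups give NaN."""
    su = u.sum(axis=0)
    sv = v.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(su > 0, sv / np.where(su > 0, su, 1.0) * a, np.nan)
    return b


def factorize_b(
    b: np.ndarray, ploidy_flags: np.ndarray | None = None, ploidy_divisor: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Factorize b_jk ~ c_j d_k by OLS on log b with type and sample
    indicators; d_1 = 1. Cell types flagged as double-ploidy get c divided by
    ``ploidy_divisor``."""
    b = np.asarray(b, dtype=float)
    K, S = b.shape
    mask = np.isfinite(b) & (b > 0)
    if not mask.any(axis=1).all():
        raise ValidationError("a cell type is observed in no sample")
    rows = np.repeat(np.arange(K), S)[mask.ravel()]
    cols = np.tile(np.arange(S), K)[mask.ravel()]
    logb = np.log(b.ravel()[mask.ravel()])
    X = np.zeros((len(logb), K + S - 1))
    X[np.arange(len(logb)), rows] = 1.0
    nonref = cols > 0
    X[np.flatnonzero(nonref), K + cols[nonref] - 1] = 1.0
    coef, *_ = np.linalg.lstsq(X, logb, rcond=None)
    c = np.exp(coef[:K])
    d = np.concatenate([[1.0], np.exp(coef[K:])])
    if ploidy_flags is not None:
        c = np.where(np.asarray(ploidy_flags, dtype=bool), c / ploidy_divisor, c)
    return c, d


# ---------------------------------------------------------------------------
# Marker selection and reference
# ---------------------------------------------------------------------------

def _welch_t(groupA: np.ndarray, groupB: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic, zero where undefined."""
    mA, mB = groupA.mean(axis=1), groupB.mean(axis=1)
    vA = groupA.var(axis=1, ddof=1) / groupA.shape[1]
    vB = groupB.var(axis=1, ddof=1) / groupB.shape[1]
    den = np.sqrt(vA + vB)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, (mA - mB) / np.where(den > 0, den, 1.0), 0.0)
    return t


def select_marker_peaks(
    v: np.ndarray,
    grid: tuple[int, ...] = tuple(range(20, 201, 20)),
    max_condition: float = 1e8,
) -> np.ndarray:
    """Choose cell-type marker peaks from quantile-normalized pseudo-bulks
    v (peaks x types x samples): rank peaks per type by Welch t (that type's
    samples vs all others); over a grid of per-type counts pick the set whose
    signature matrix has the smallest condition number."""
    P, K, S = v.shape
    if K < 2:
        raise ConfigurationError("need >= 2 cell types")
    flat = v.reshape(P, K * S)
    ranks = []
    for j in range(K):
        A = v[:, j, :]
        B = np.delete(v, j, axis=1).reshape(P, (K - 1) * S)
        if A.shape[1] < 2:
            warnings.warn(f"cell type {j} has <2 samples; using fold change")
            t = np.log1p(A.mean(axis=1)) - np.log1p(B.mean(axis=1))
        else:
            t = _welch_t(A, B)
        ranks.append(np.argsort(-t, kind="stable"))
    W_full = v.mean(axis=2)
    best_cond, best_set = np.inf, None
    for m in grid:
        selected = np.unique(np.concatenate([r[:m] for r in ranks]))
        cond = np.linalg.cond(W_full[selected])
        if cond < best_cond:
            best_cond, best_set = cond, selected
    if best_set is None or not np.isfinite(best_cond) or best_cond > max_condition:
        raise ValidationError(
            f"signature matrix ill-conditioned (condition number {best_cond:.3g}); "
            "cell-type profiles are not identifiable"
        )
    return best_set


def _quartile_cap(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Cap values to [Q1^2/Q2, Q3^2/Q2] of their own quartiles."""
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    if q2 <= 0:
        return values.copy(), -np.inf, np.inf
    lo, hi = q1**2 / q2, q3**2 / q2
    return np.clip(values, lo, hi), lo, hi


@dataclass
class DeconvolutionReference:
    peaks: np.ndarray  # selected peak indices
    W: np.ndarray  # selected peaks x types
    e2: np.ndarray  # uncapped per-peak error variance
    e2_capped: np.ndarray
    c: np.ndarray  # nuclei-equivalent scalar per type
    d: np.ndarray  # per-sample batch scalar, d[0] = 1
    quantile_ref: np.ndarray  # full-length reference distribution
    f: np.ndarray | None = None  # per-peak platform factor on selected peaks
    type_names: list = field(default_factory=list)


def build_reference(
    v: np.ndarray,
    selected: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    quantile_ref: np.ndarray,
    type_names: list | None = None,
) -> DeconvolutionReference:
    """Signature matrix W (mean over samples) and per-peak error variance
    e^2 (mean over types of the across-sample variance) on the selected
    peaks; a quartile-capped copy of e^2 is stored for regression weights."""
    vt = v[selected]
    W = vt.mean(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        var_k = np.nanvar(vt, axis=2, ddof=1) if vt.shape[2] > 1 else np.zeros(W.shape)
    e2 = np.nan_to_num(var_k).mean(axis=1)
    if np.all(e2 == 0):
        e2_capped = e2.copy()
    else:
        e2_capped, _, _ = _quartile_cap(e2)
    return DeconvolutionReference(
        peaks=np.asarray(selected),
        W=W,
        e2=e2,
        e2_capped=e2_capped,
        c=np.asarray(c, dtype=float),
        d=np.asarray(d, dtype=float),
        quantile_ref=np.asarray(quantile_ref, dtype=float),
        type_names=list(type_names or range(W.shape[1])),
    )


def synthesize_mixture(ref: DeconvolutionReference, a_k: np.ndarray) -> np.ndarray:
    """Pseudo-bulk mixture for a matched sample with nucleus counts a_k:
    x = sum_j a_jk / (sum_j' a_j'k) * (1/c_j) * w_j, scaled to one nucleus."""
    a_k = np.asarray(a_k, dtype=float)
    props = a_k / a_k.sum()
    return ref.W @ (props / ref.c)


def platform_correction(
    x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Per-peak platform factor: f_i = exp(mean_k log(y_ik / x_ik)) over
    matched samples (columns), quartile-capped. Nonpositive pairs are excluded
    pairwise; peaks with no usable pair get f = 1."""
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    y = np.atleast_2d(np.asarray(y, dtype=float).T).T
    ok = (x > 0) & (y > 0)
    if not ok.all():
        warnings.warn("nonpositive matched entries excluded from platform factors")
    with np.errstate(divide="ignore", invalid="ignore"):
        logratio = np.where(ok, np.log(np.where(ok, y, 1.0) / np.where(ok, x, 1.0)), np.nan)
    n_ok = ok.sum(axis=1)
    f = np.ones(x.shape[0])
    has = n_ok > 0
    f[has] = np.exp(np.nansum(logratio[has], axis=1) / n_ok[has])
    if not has.all():
        warnings.warn("peaks without positive matched pairs got platform factor 1")
    f_capped, _, _ = _quartile_cap(f)
    return f_capped


# ---------------------------------------------------------------------------
# Deconvolution
# ---------------------------------------------------------------------------

@dataclass
class CompositionEstimate:
    theta: np.ndarray
    composition: np.ndarray
    sigma: float
    diagnostics: dict


def deconvolve(
    y: np.ndarray,
    ref: DeconvolutionReference,
    *,
    prenormalized: bool = False,
    method: str = "huber",
    huber_t: float = 1.345,
    condition_warn: float = 1e4,
) -> CompositionEstimate:
    """Estimate the cell-type composition of one bulk vector.

    The full-length bulk vector is quantile normalized to the stored
    reference, restricted to the selected peaks, platform-corrected
    (F^-1 y) and regressed on W with per-peak weights 1/e_i from the capped
    error variances (equal weights when e^2 is all zero). ``method`` is
    'huber' (M-estimation, the default), 'bisquare', or 'nnls'. Negative
    coefficients are clamped at zero and the composition rescaled as
    c_j theta_j / sum_j c_j theta_j.
    """
    y = np.asarray(y, dtype=float)
    if prenormalized:
        ysel = y if len(y) == len(ref.peaks) else y[ref.peaks]
    else:
        yn, _ = quantile_normalize(y[:, None], ref.quantile_ref)
        ysel = yn[:, 0][ref.peaks]
    if ref.f is not None:
        ysel = ysel / ref.f
    W = ref.W
    e2 = ref.e2_capped
    if np.all(e2 == 0):
        wts = np.ones(len(ysel))
    else:
        # zero error variances (exact replicates) fall back to the smallest
        # observed positive variance rather than an infinite weight
        floor = e2[e2 > 0].min()
        wts = 1.0 / np.sqrt(np.maximum(e2, floor))
    yw = ysel * wts
    Ww = W * wts[:, None]
    if method == "nnls":
        theta, _ = scipy.optimize.nnls(Ww, yw)
        resid = yw - Ww @ theta
        sigma = float(np.std(resid))
    elif method in ("huber", "bisquare"):
        norm = (sm.robust.norms.HuberT(t=huber_t) if method == "huber"
                else sm.robust.norms.TukeyBiweight())
        fit = sm.RLM(yw, Ww, M=norm).fit()
        theta = fit.params
        sigma = float(fit.scale)
        resid = yw - Ww @ theta
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    n_clamped = int((theta < 0).sum())
    theta = np.maximum(theta, 0.0)
    total = float(ref.c @ theta)
    if total <= 0:
        raise ValidationError("all estimated coefficients nonpositive")
    composition = ref.c * theta / total
    cond = float(np.linalg.cond(W))
    if cond > condition_warn:
        warnings.warn(f"signature matrix condition number {cond:.3g}")
    return CompositionEstimate(
        theta=theta,
        composition=composition,
        sigma=sigma,
        diagnostics={
            "n_clamped": n_clamped,
            "residual_norm": float(np.linalg.norm(resid)),
            "condition_number": cond,
            "c_theta_total": total,
        },
    )


def build_pipeline_reference(
    u: np.ndarray,
    a: np.ndarray,
    ploidy_flags: np.ndarray | None = None,
    *,
    grid: tuple[int, ...] = tuple(range(20, 201, 20)),
    type_names: list | None = None,
) -> DeconvolutionReference:
    """Convenience chain from pseudo-bulk counts u (peaks x types x samples)
    and nucleus counts a (types x samples) to a ready reference: quantile
    normalization, nuclei-equivalent factorization, marker selection, W and
    e^2."""
    P, K, S = u.shape
    flat_u = u.reshape(P, K * S)
    v_flat, ref_dist = quantile_normalize(flat_u)
    v = v_flat.reshape(P, K, S)
    b = nuclei_equivalents(flat_u, v_flat, np.asarray(a, dtype=float).reshape(-1))
    c, d = factorize_b(b.reshape(K, S), ploidy_flags)
    selected = select_marker_peaks(v, grid=grid)
    return build_reference(v, selected, c, d, ref_dist, type_names)


def normalize_bulk_cohort(
    y: np.ndarray, ref: DeconvolutionReference
) -> np.ndarray:
    """Quantile normalize full-length bulk vectors (peaks x samples).

    With two or more bulk samples the cohort is normalized jointly to its own
    mean distribution, which keeps each vector a nearly linear image of its
    raw counts; the systematic per-peak offset between bulk and pseudo-bulk
    space is then absorbed by the platform factors. A single bulk sample falls
    back to the stored pseudo-bulk reference distribution.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if y.shape[1] >= 2:
        yn, _ = quantile_normalize(y)
    else:
        yn, _ = quantile_normalize(y, ref.quantile_ref)
    return yn


def fit_platform_factors(
    ref: DeconvolutionReference,
    a_matched: np.ndarray,
    y_matched_normalized: np.ndarray,
) -> np.ndarray:
    """Platform factors from matched samples: synthesize pseudo-bulk mixtures
    x_k from the reference and the matched nucleus counts (types x samples),
    and take capped per-peak geometric-mean ratios against the normalized
    bulk vectors restricted to the selected peaks."""
    a_matched = np.asarray(a_matched, dtype=float)
    x = np.column_stack([synthesize_mixture(ref, a_matched[:, k])
                         for k in range(a_matched.shape[1])])
    return platform_correction(x, y_matched_normalized[ref.peaks])


def composition_standard_error(sd: float, n_animals: int) -> float:
    """SE of a mean composition over n animals given the per-sample SD."""
    return sd / np.sqrt(n_animals)


# ---------------------------------------------------------------------------
# Condition comparison
# ---------------------------------------------------------------------------

def compare_compositions(
    compositions: pd.DataFrame,
    conditions: np.ndarray,
    reference_condition: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per cell type, OLS of composition on condition indicators (reference
    condition as baseline); two-sided t-test per coefficient, Bonferroni
    threshold alpha / (n_types * n_non-reference_conditions)."""
    conditions = np.asarray(conditions)
    levels = [c for c in pd.unique(conditions) if c != reference_condition]
    if not levels:
        raise ConfigurationError("need at least one non-reference condition")
    X = np.column_stack([np.ones(len(conditions))]
                        + [(conditions == c).astype(float) for c in levels])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular condition design")
    threshold = alpha / (compositions.shape[1] * len(levels))
    rows = []
    for ct in compositions.columns:
        fit = sm.OLS(compositions[ct].to_numpy(), X).fit()
        for i, cond in enumerate(levels, start=1):
            p = float(fit.pvalues[i])
            rows.append((ct, cond, float(fit.params[i]), p, p < threshold))
    out = pd.DataFrame(rows, columns=["cell_type", "condition", "coef", "p", "significant"])
    out.attrs["threshold"] = threshold
    return out
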