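"""IDF-weighted, batch-corrected latent semantic indexing and two-pass
clustering of the binary site x nucleus accessibility matrix.

The matrix entry g_i * d_j * f_ij * gamma_ij combines an inverse document
frequency weight per site (g), a document normalization per nucleus (d), the
binary accessibility value (f), and a per-sample (optionally per-cell-type)
batch-correction factor (gamma). Rows are centred, a truncated SVD taken, and
nuclei clustered on the V*D coordinates via a shared-nearest-neighbor graph
and Leiden modularity optimization. The full procedure runs twice: first with
sample-only batch correction to get a coarse cell-type grouping, then with the
refined per-cell-type correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import scipy.linalg
from sklearn.neighbors import NearestNeighbors

from .io import ConfigurationError, ValidationError


# ---------------------------------------------------------------------------
# LSI ingredients
# ---------------------------------------------------------------------------

def idf_weights(f: np.ndarray) -> np.ndarray:
    """g_i = log2(n / sum_j f_ij) per site; sites open in every nucleus get 0."""
    f = np.asarray(f)
    n = f.shape[1]
    row_sums = f.sum(axis=1)
    if (row_sums == 0).any():
        raise ValidationError("all-zero site row; exclude empty sites first")
    return np.log2(n / row_sums)


def variance_filter(f: np.ndarray, g: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of sites whose IDF-weighted variance g^2 p (1-p) exceeds the
    threshold (0.4 for 500-bp tile matrices, 0.1 for peak matrices)."""
    p = np.asarray(f).sum(axis=1) / f.shape[1]
    return np.flatnonzero(g**2 * p * (1 - p) > threshold)


def document_norm(f: np.ndarray, kind: str = "sum") -> np.ndarray:
    """d_j = 1 / sum_i f_ij^2 per nucleus (``kind='sum'``, the default);
    ``kind='l2'`` uses the conventional 1 / sqrt(sum f^2) L2 document norm."""
    col = np.asarray(f).sum(axis=0).astype(float)  # binary: sum f^2 == sum f
    if (col == 0).any():
        raise ValidationError("nucleus with no open retained site")
    if kind == "sum":
        return 1.0 / col
    if kind == "l2":
        return 1.0 / np.sqrt(col)
    raise ConfigurationError(f"unknown document_norm kind {kind!r}")


def batch_correction(
    f: np.ndarray,
    d: np.ndarray,
    samples: np.ndarray,
    coarse_labels: np.ndarray | None = None,
) -> np.ndarray:
    """Per-entry batch factor gamma (sites x nuclei).

    Without coarse labels: gamma_ij = mean over all nuclei of d*f on site i
    divided by the mean over the nuclei of j's sample. With coarse labels both
    means are restricted to j's cell type. Zero denominators give gamma = 1.
    Per nucleus, gamma is capped above at Q3^2/Q2 of its own gamma values over
    sites.
    """
    f = np.asarray(f, dtype=float)
    samples = np.asarray(samples)
    if f.shape[1] != len(samples):
        raise ValidationError("sample labels do not match nucleus count")
    df = f * d[None, :]
    gamma = np.ones_like(f)

    if coarse_labels is None:
        groups = [("", np.ones(f.shape[1], dtype=bool))]
    else:
        coarse_labels = np.asarray(coarse_labels)
        groups = [(c, coarse_labels == c) for c in np.unique(coarse_labels)]

    for _, cmask in groups:
        num = df[:, cmask].mean(axis=1)  # per site
        for s in np.unique(samples):
            jmask = cmask & (samples == s)
            if not jmask.any():
                continue
            den = df[:, jmask].mean(axis=1)
            ratio = np.ones_like(num)
            nz = den > 0
            ratio[nz] = num[nz] / den[nz]
            gamma[:, jmask] = ratio[:, None]

    # per-nucleus cap at Q3^2 / Q2 over sites
    q2 = np.percentile(gamma, 50, axis=0)
    q3 = np.percentile(gamma, 75, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cap = np.where(q2 > 0, q3**2 / q2, np.inf)
    return np.minimum(gamma, cap[None, :])


@dataclass
class EmbeddingResult:
    singular_values: np.ndarray
    coordinates: np.ndarray  # nuclei x components (V * D)
    n_components: int
    site_index: np.ndarray | None = None
    idf: np.ndarray | None = None
    doc_norm: np.ndarray | None = None


def embed(
    f: np.ndarray,
    g: np.ndarray,
    d: np.ndarray,
    gamma: np.ndarray | float = 1.0,
    n_components: int = 30,
) -> EmbeddingResult:
    """Row-centred truncated SVD of (g_i d_j f_ij gamma_ij); nucleus
    coordinates are V * D for the leading components."""
    f = np.asarray(f, dtype=float)
    if n_components > min(f.shape):
        raise ValidationError("n_components exceeds matrix dimensions")
    X = g[:, None] * d[None, :] * f * gamma
    X = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    s = s[:n_components]
    coords = Vt[:n_components].T * s[None, :]
    return EmbeddingResult(s, coords, n_components)


def remove_outliers(
    coords_2d: np.ndarray, k: int = 5, percentile: float = 99.5
) -> np.ndarray:
    """Flag nuclei whose summed squared distance to their k nearest
    neighbours lies above the given percentile. Fewer than k+1 points: no
    flags."""
    coords_2d = np.asarray(coords_2d)
    n = len(coords_2d)
    flags = np.zeros(n, dtype=bool)
    if n < k + 1:
        return flags
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords_2d)
    dist, _ = nn.kneighbors(coords_2d)
    score = (dist[:, 1:] ** 2).sum(axis=1)
    return score > np.percentile(score, percentile)


def knn_outlier_score(coords: np.ndarray, k: int = 5) -> np.ndarray:
    """Sum of squared distances to the k nearest neighbours."""
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    return (dist[:, 1:] ** 2).sum(axis=1)


# ---------------------------------------------------------------------------
# SNN + Leiden clustering
# ---------------------------------------------------------------------------

def snn_graph(coords: np.ndarray, k: int = 20, prune: float = 1 / 15) -> igraph.Graph:
    """Shared-nearest-neighbor graph: kNN sets, Jaccard edge weights, edges
    below ``prune`` dropped."""
    n = len(coords)
    if k >= n:
        raise ValidationError("k must be smaller than the number of nuclei")
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(coords)
    neighbor_sets = [set(row) for row in idx]
    edges, weights = [], []
    seen = set()
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            a, b = (i, j) if i < j else (j, i)
            if a == b or (a, b) in seen:
                continue
            seen.add((a, b))
            inter = len(neighbor_sets[a] & neighbor_sets[b])
            jac = inter / (2 * k - inter)
            if jac >= prune:
                edges.append((a, b))
                weights.append(jac)
    graph = igraph.Graph(n=n, edges=edges)
    graph.es["weight"] = weights
    return graph


def cluster(
    coords: np.ndarray,
    k: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    prune: float = 1 / 15,
) -> np.ndarray:
    """Leiden modularity clustering on the SNN graph; labels are contiguous
    integers ordered by cluster size."""
    graph = snn_graph(coords, k=k, prune=prune)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    order = np.argsort([-np.sum(labels == c) for c in range(labels.max() + 1)],
                       kind="stable")
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(l)] for l in labels])


def merge_coarse(
    coords_2d: np.ndarray,
    fine_labels: np.ndarray,
    merge_fraction: float = 0.25,
    override: dict[int, int] | None = None,
) -> np.ndarray:
    """Agglomerate fine clusters whose top-2-component centroids lie within
    ``merge_fraction`` of the global coordinate spread; ``override`` maps fine
    labels directly to coarse labels."""
    if override is not None:
        return np.array([override[int(l)] for l in fine_labels])
    labels = np.unique(fine_labels)
    centroids = np.vstack([coords_2d[fine_labels == c].mean(axis=0) for c in labels])
    spread = np.linalg.norm(coords_2d.max(axis=0) - coords_2d.min(axis=0))
    threshold = merge_fraction * spread if spread > 0 else 0.0
    # single-linkage agglomeration over centroids
    parent = list(range(len(labels)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if np.linalg.norm(centroids[i] - centroids[j]) <= threshold:
                parent[find(i)] = find(j)
    roots = {find(i) for i in range(len(labels))}
    root_map = {r: n for n, r in enumerate(sorted(roots))}
    fine_to_coarse = {int(labels[i]): root_map[find(i)] for i in range(len(labels))}
    return np.array([fine_to_coarse[int(l)] for l in fine_labels])


# ---------------------------------------------------------------------------
# Two-pass pipeline and cell-type assignment
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    fine: np.ndarray
    coarse: np.ndarray
    outlier: np.ndarray  # over the original nuclei
    kept_index: np.ndarray  # indices of non-outlier nuclei
    cell_type: np.ndarray | None = None


def two_pass_pipeline(
    f: np.ndarray,
    samples: np.ndarray,
    *,
    variance_threshold: float = 0.1,
    n_components_pass1: int = 10,
    n_components_pass2: int = 8,
    n_components_full: int = 30,
    k: int = 20,
    resolution: float = 1.0,
    outlier_percentile: float = 99.5,
    merge_fraction: float = 0.25,
    document_norm_kind: str = "sum",
    seed: int = 0,
) -> tuple[ClusterAssignment, EmbeddingResult]:
    """Full two-pass embedding/clustering.

    Pass 1: sample-level batch correction, 30-component SVD, outlier removal
    on the top-2 coordinates, re-embedding, fine clustering, coarse merge.
    Pass 2: cell-type-aware batch correction using the coarse labels,
    re-embedding, final clustering.
    """
    f = np.asarray(f)
    samples = np.asarray(samples)
    g0 = idf_weights(f)
    keep_sites = variance_filter(f, g0, variance_threshold)
    if len(keep_sites) == 0:
        raise ValidationError("variance filter removed every site")
    fr = f[keep_sites]
    nonempty = fr.sum(axis=0) > 0
    if not nonempty.all():
        raise ValidationError("nucleus with no open retained site after filtering")

    g = idf_weights(fr)
    d = document_norm(fr, document_norm_kind)
    gamma1 = batch_correction(fr, d, samples)
    full = embed(fr, g, d, gamma1, min(n_components_full, min(fr.shape)))
    outlier = remove_outliers(full.coordinates[:, :2], percentile=outlier_percentile)
    kept = np.flatnonzero(~outlier)

    fk = fr[:, kept]
    open_sites = fk.sum(axis=1) > 0
    fk = fk[open_sites]
    gk = idf_weights(fk)
    dk = document_norm(fk, document_norm_kind)
    sk = samples[kept]
    gamma1k = batch_correction(fk, dk, sk)
    emb1 = embed(fk, gk, dk, gamma1k, n_components_pass1)
    fine1 = cluster(emb1.coordinates, k=k, resolution=resolution, seed=seed)
    coarse = merge_coarse(emb1.coordinates[:, :2], fine1, merge_fraction)

    gamma2 = batch_correction(fk, dk, sk, coarse)
    emb2 = embed(fk, gk, dk, gamma2, n_components_pass2)
    fine2 = cluster(emb2.coordinates, k=k, resolution=resolution, seed=seed)

    emb2.site_index = keep_sites[open_sites]
    emb2.idf = gk
    emb2.doc_norm = dk
    assignment = ClusterAssignment(fine=fine2, coarse=coarse, outlier=outlier,
                                   kept_index=kept)
    return assignment, emb2


def assign_cell_types(
    clusters: np.ndarray,
    gene_scores,  # DataFrame genes x nuclei
    markers: dict[str, list[str]],
    tie_tolerance: float = 1e-9,
) -> dict[int, str]:
    """Label each cluster with the cell type whose marker genes have the
    highest mean standardized accessibility score; near-ties (within
    ``tie_tolerance``) become 'ambiguous'. Markers absent from the matrix are
    skipped."""
    import pandas as pd

    vals = gene_scores.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = pd.DataFrame((vals - mu) / sd, index=gene_scores.index,
                     columns=gene_scores.columns)
    out: dict[int, str] = {}
    for c in np.unique(clusters):
        nuclei = np.flatnonzero(clusters == c)
        scores = {}
        for ct in sorted(markers):
            present = [m for m in markers[ct] if m in z.index]
            if not present:
                continue
            scores[ct] = float(z.loc[present].iloc[:, nuclei].to_numpy().mean())
        if not scores:
            out[int(c)] = "ambiguous"
            continue
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] - ranked[1][1] < tie_tolerance:
            out[int(c)] = "ambiguous"
        else:
            out[int(c)] = ranked[0][0]
    return out


DEFAULT_MARKERS = {
    "hepatocyte": ["Alb", "Apoc3", "Cyp2e1", "Cyp2f4"],
    "cholangiocyte": ["Epcam", "Krt19"],
    "endothelial": ["Stab2"],
    "stellate": ["Dcn", "Des", "Lrat", "Acta2"],
    "macrophage": ["Csf1r"],
    "inflammatory_macrophage": ["Lyz2"],
    "noninflammatory_macrophage": ["Marco"],
    "t_cell": ["Cd3g", "Gata3"],
    "nk_t_cell": ["Gzma", "Prf1"],
    "b_cell": ["Ebf1"],
}
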