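"""Synthetic-data generators with recorded ground truth.

Every input the pipeline consumes can be produced here: per-nucleus Tn5
fragments with TSS pileups and nucleosome-periodic size distributions, binary
site x nucleus matrices with cell-type structure and per-sample depth batch
effects, pseudo-bulk mixtures with known proportions and per-peak platform
distortion, TF-deviation / gene-score matrices with planted regulatory
modules, gene sets overlapping those modules, and a module-enriched PPI
network.

Noise families are the simplest ones matching the data: Poisson counts,
log-normal multiplicative batch/platform factors, Gaussian residuals. A
``noise_free`` flag on the mixture generator returns expectations instead of
samples so exact-recovery tests are possible.

The synthetic genome has ``n_chromosomes`` chromosomes of decreasing length
with a TSS every 100 kb; 21 chromosomes by default (a rat-like autosome count)
so per-chromosome statistics behave like real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ConfigurationError, FragmentSet, GeneSet, PPINetwork

TSS_SPACING = 100_000


@dataclass
class SyntheticConfig:
    """Study-scale defaults: 7 liver cell types, 5 samples/conditions,
    4 planted regulatory modules."""

    n_cell_types: int = 7
    n_nuclei_per_sample: int = 300
    n_samples: int = 5
    n_peaks: int = 1000
    n_tiles: int = 2000
    n_genes: int = 300
    n_tfs: int = 50
    n_conditions: int = 5
    n_modules: int = 4
    depth_batch_sd: float = 0.3
    platform_sd: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_cell_types=self.n_cell_types,
            n_nuclei_per_sample=self.n_nuclei_per_sample,
            n_samples=self.n_samples,
            n_peaks=self.n_peaks,
            n_tiles=self.n_tiles,
            n_genes=self.n_genes,
            n_tfs=self.n_tfs,
            n_conditions=self.n_conditions,
            n_modules=self.n_modules,
        )
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value}")
        for name in ("depth_batch_sd", "platform_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_modules > min(self.n_tfs, self.n_genes):
            raise ConfigurationError("n_modules must be <= min(n_tfs, n_genes)")


@dataclass
class SyntheticTruth:
    """Ground-truth labels/parameters actually used in sampling."""

    nucleus_cell_type: np.ndarray | None = None
    nucleus_sample: np.ndarray | None = None
    condition_of_nucleus: np.ndarray | None = None
    mixture_proportions: np.ndarray | None = None  # samples x cell types
    platform_factors: np.ndarray | None = None
    ploidy_flags: np.ndarray | None = None
    module_of_tf: np.ndarray | None = None  # -1 for non-members
    module_of_gene: np.ndarray | None = None
    gs_membership: dict[str, list[str]] | None = None
    contaminated: np.ndarray | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def _chromosomes(n_chromosomes: int) -> tuple[list[str], np.ndarray]:
    """Decreasing chromosome lengths, 3 Mb down to >= 1 Mb."""
    lengths = np.linspace(3_000_000, 1_000_000, n_chromosomes).astype(int)
    names = [f"chr{i + 1}" for i in range(n_chromosomes)]
    return names, lengths


def tss_positions(n_chromosomes: int = 21) -> pd.DataFrame:
    """Synthetic TSS annotation: one TSS every 100 kb on every chromosome."""
    names, lengths = _chromosomes(n_chromosomes)
    rows = []
    for name, length in zip(names, lengths):
        for pos in range(TSS_SPACING // 2, length - TSS_SPACING // 2, TSS_SPACING):
            rows.append((name, pos))
    return pd.DataFrame(rows, columns=["chrom", "tss"])


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

def _fragment_sizes(rng, n, periodic_weight):
    """Sub-nucleosomal exponential plus Gaussians at 200 and 400 bp."""
    periodic = rng.random(n) < periodic_weight
    sizes = np.empty(n)
    n_per = int(periodic.sum())
    # periodic component: mono-/di-nucleosome peaks at 200 and 400 bp
    mono = rng.random(n_per) < 0.7
    mu = np.where(mono, 200.0, 400.0)
    sizes[periodic] = rng.normal(mu, 20.0)
    sizes[~periodic] = 40.0 + rng.exponential(45.0, n - n_per)
    return np.clip(np.round(sizes), 10, 990).astype(int)


def generate_fragments(
    config: SyntheticConfig,
    *,
    n_nuclei: int | None = None,
    depth: int = 2000,
    tss_fraction: float = 0.5,
    periodic_weight: float = 0.5,
    contaminated_fraction: float = 0.0,
    contamination_sd: float = 3.0,
    n_chromosomes: int = 21,
) -> tuple[FragmentSet, SyntheticTruth]:
    """Per-nucleus Tn5 fragments on the synthetic genome.

    ``tss_fraction`` of fragments are centred within 500 bp of a TSS (hence
    inside the TSS +/- 1 kb window); the rest fall uniformly on chromosomes in
    proportion to length. ``contamination_sd`` perturbs a contaminated
    nucleus's chromosome allocation, expressed in units of the multinomial
    sampling SD of per-chromosome proportions at the target depth.
    """
    if not 0 <= tss_fraction <= 1 or not 0 <= periodic_weight <= 1:
        raise ConfigurationError("fractions must lie in [0, 1]")
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    rng = np.random.default_rng(config.seed)
    if n_nuclei is None:
        n_nuclei = config.n_nuclei_per_sample
    names, lengths = _chromosomes(n_chromosomes)
    chrom_p = lengths / lengths.sum()
    tss = tss_positions(n_chromosomes)
    tss_by_chrom = {c: g["tss"].to_numpy() for c, g in tss.groupby("chrom")}

    n_contam = int(round(contaminated_fraction * n_nuclei))
    contaminated = np.zeros(n_nuclei, dtype=bool)
    contaminated[:n_contam] = True

    tables = []
    for j in range(n_nuclei):
        barcode = f"N{j:05d}"
        n_frag = max(1, rng.poisson(depth))
        p = chrom_p
        if contaminated[j]:
            sd = np.sqrt(chrom_p * (1 - chrom_p) / depth)
            signs = rng.choice([-1.0, 1.0], size=len(chrom_p))
            p = np.clip(chrom_p + contamination_sd * sd * signs, 1e-6, None)
            p = p / p.sum()
        chrom_idx = rng.choice(len(names), size=n_frag, p=p)
        sizes = _fragment_sizes(rng, n_frag, periodic_weight)
        at_tss = rng.random(n_frag) < tss_fraction
        centers = np.empty(n_frag, dtype=int)
        for i in range(n_frag):
            c = chrom_idx[i]
            if at_tss[i]:
                sites = tss_by_chrom[names[c]]
                centers[i] = rng.choice(sites) + rng.integers(-500, 501)
            else:
                centers[i] = rng.integers(1000, lengths[c] - 1000)
        start = np.maximum(0, centers - sizes // 2)
        end = start + sizes
        tables.append(
            pd.DataFrame(
                {
                    "chrom": [names[c] for c in chrom_idx],
                    "start": start,
                    "end": end,
                    "barcode": barcode,
                    "count": 1,
                }
            )
        )
    data = pd.concat(tables, ignore_index=True)
    frags = FragmentSet(data, {f"N{j:05d}": "s1" for j in range(n_nuclei)})
    truth = SyntheticTruth(contaminated=contaminated)
    return frags, truth


# ---------------------------------------------------------------------------
# Binary accessibility matrix
# ---------------------------------------------------------------------------

def generate_binary_matrix(
    config: SyntheticConfig,
    *,
    baseline_prob: float = 0.02,
    signature_prob: float = 0.4,
    profile: np.ndarray | None = None,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Binary site x nucleus matrix with cell-type structure and per-sample
    depth batch effects.

    Each cell type gets a private block of signature sites opened at
    ``signature_prob`` on top of a shared ``baseline_prob``; a per-sample
    multiplier exp(N(0, depth_batch_sd^2)) scales all open probabilities
    (clipped to [0, 1]). ``profile`` (sites x cell types) overrides the block
    design when given.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_sites, K = config.n_tiles, config.n_cell_types
    if profile is None:
        profile = np.full((n_sites, K), baseline_prob)
        block = n_sites // (K + 1)
        for k in range(K):
            profile[k * block : (k + 1) * block, k] = signature_prob
    n = config.n_samples * config.n_nuclei_per_sample
    sample = np.repeat([f"s{i + 1}" for i in range(config.n_samples)],
                       config.n_nuclei_per_sample)
    cell_type = rng.integers(0, K, size=n)
    depth_mult = np.exp(rng.normal(0.0, config.depth_batch_sd, config.n_samples))
    sample_idx = np.repeat(np.arange(config.n_samples), config.n_nuclei_per_sample)
    probs = profile[:, cell_type] * depth_mult[sample_idx][None, :]
    probs = np.clip(probs, 0.0, 1.0)
    f = (rng.random(probs.shape) < probs).astype(np.int8)
    truth = SyntheticTruth(
        nucleus_cell_type=cell_type,
        nucleus_sample=sample,
        extra={"depth_multipliers": depth_mult, "profile_shape": profile.shape},
    )
    return f, truth


# ---------------------------------------------------------------------------
# Mixture experiment for deconvolution
# ---------------------------------------------------------------------------

def generate_mixture_experiment(
    config: SyntheticConfig,
    *,
    n_mixtures: int = 5,
    sn_depth: float = 1000.0,
    bulk_depth: float = 2e6,
    total_nuclei: int = 2000,
    noise_free: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, SyntheticTruth]:
    """Matched single-nucleus / bulk mixture experiment.

    Returns ``(u, a, y, truth)``: pseudo-bulk counts ``u`` (peaks x types x
    samples), nucleus counts ``a`` (types x samples), bulk counts ``y``
    (peaks x samples). Per-nucleus single-nucleus depth is droplet-limited and
    identical across cell types, while in the bulk assay each nucleus of the
    ploidy-flagged type (type 0) contributes twice the signal — so correct
    composition recovery requires halving that type's nuclei-equivalent
    scalar.
    """
    rng = np.random.default_rng(config.seed + 2)
    P, K = config.n_peaks, config.n_cell_types
    # per-type peak intensity profiles: each type arranges the same lognormal
    # intensity multiset differently (same assay, same value distribution,
    # type-specific peak usage) so quantile normalization is distribution-
    # preserving and marker peaks arise from the arrangement differences
    base = np.exp(rng.normal(0.0, 1.0, size=P))
    s = np.column_stack([base[rng.permutation(P)] for _ in range(K)])
    s /= s.sum(axis=0, keepdims=True)

    props = rng.dirichlet(np.ones(K), size=n_mixtures)  # samples x types
    a = np.maximum(1, np.round(total_nuclei * props.T)).astype(int)  # K x n_mix

    lam_u = a[None, :, :] * sn_depth * s[:, :, None]
    u = lam_u if noise_free else rng.poisson(lam_u).astype(float)

    ploidy = np.ones(K)
    ploidy[0] = 2.0
    f_true = np.exp(rng.normal(0.0, config.platform_sd, size=P))
    mix = s @ (props * ploidy[None, :]).T  # peaks x samples
    mix = mix / mix.sum(axis=0, keepdims=True)
    lam_y = bulk_depth * (f_true[:, None] * mix)
    lam_y = lam_y / lam_y.sum(axis=0, keepdims=True) * bulk_depth
    y = lam_y if noise_free else rng.poisson(lam_y).astype(float)

    truth = SyntheticTruth(
        mixture_proportions=props,
        platform_factors=f_true,
        ploidy_flags=(ploidy > 1),
        extra={"intensity_profiles": s},
    )
    return u, a.astype(float), y, truth


# ---------------------------------------------------------------------------
# Regulatory dataset (planted modules)
# ---------------------------------------------------------------------------

def _assign_modules(rng, n_items: int, n_modules: int, member_fraction: float):
    labels = np.full(n_items, -1, dtype=int)
    n_members = int(round(member_fraction * n_items))
    n_members -= n_members % n_modules  # equal module sizes
    idx = rng.permutation(n_items)[:n_members]
    labels[idx] = np.arange(n_members) % n_modules
    return labels


def generate_regulatory_dataset(
    config: SyntheticConfig,
    *,
    member_fraction: float = 0.8,
    loading_range: tuple[float, float] = (0.8, 1.5),
    condition_effect: float = 1.0,
    gs_fraction: float = 0.8,
    ppi_in_score: float = 0.9,
    ppi_out_score: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[GeneSet], PPINetwork, SyntheticTruth]:
    """TF-deviation and gene-score matrices with planted modules.

    Each module m has a latent per-nucleus activity factor whose mean is
    shifted by condition; member TF/gene rows are loading * factor +
    N(0, noise_sd^2); non-members are pure noise. One gene set per module
    holds ``gs_fraction`` of that module's genes plus decoy genes; matched-size
    decoy sets are added. PPI edges between symbols sharing a module score
    around ``ppi_in_score``; background edges around ``ppi_out_score``.
    """
    rng = np.random.default_rng(config.seed + 3)
    M = config.n_modules
    n = config.n_samples * config.n_nuclei_per_sample
    sample = np.repeat([f"s{i + 1}" for i in range(config.n_samples)],
                       config.n_nuclei_per_sample)
    condition = np.array([f"c{(int(s[1:]) - 1) % config.n_conditions + 1}"
                          for s in sample])
    cond_idx = np.array([int(c[1:]) - 1 for c in condition])
    shifts = rng.normal(0.0, condition_effect, size=(config.n_conditions, M))
    factors = shifts[cond_idx] + rng.normal(0.0, 1.0, size=(n, M))  # n x M

    module_of_tf = _assign_modules(rng, config.n_tfs, M, member_fraction)
    module_of_gene = _assign_modules(rng, config.n_genes, M, member_fraction)

    tf_names = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    gene_names = [f"G{i + 1:04d}" for i in range(config.n_genes)]

    def _rows(labels, n_rows):
        X = rng.normal(0.0, config.noise_sd, size=(n_rows, n))
        for r, m in enumerate(labels):
            if m >= 0:
                loading = rng.uniform(*loading_range)
                X[r] += loading * factors[:, m]
        return X

    tf_matrix = pd.DataFrame(_rows(module_of_tf, config.n_tfs),
                             index=tf_names)
    gene_matrix = pd.DataFrame(_rows(module_of_gene, config.n_genes),
                               index=gene_names)

    gene_arr = np.array(gene_names)
    gene_sets: list[GeneSet] = []
    membership: dict[str, list[str]] = {}
    for m in range(M):
        module_genes = gene_arr[module_of_gene == m]
        n_in = max(1, int(round(gs_fraction * len(module_genes))))
        chosen = list(rng.choice(module_genes, size=n_in, replace=False))
        pool = gene_arr[module_of_gene != m]
        n_decoy = max(1, int(round(0.2 * n_in)))
        chosen += list(rng.choice(pool, size=n_decoy, replace=False))
        gene_sets.append(GeneSet(f"GS_module{m + 1}", frozenset(chosen), "planted"))
        membership[f"GS_module{m + 1}"] = chosen
    for m in range(M):
        size = len(membership[f"GS_module{m + 1}"])
        chosen = list(rng.choice(gene_arr, size=size, replace=False))
        gene_sets.append(GeneSet(f"GS_decoy{m + 1}", frozenset(chosen), "decoy"))
        membership[f"GS_decoy{m + 1}"] = chosen

    # PPI: dense within modules (TFs and genes), sparse background
    symbols = tf_names + gene_names
    module_of_symbol = np.concatenate([module_of_tf, module_of_gene])
    edges = []
    for m in range(M):
        members = [symbols[i] for i in np.flatnonzero(module_of_symbol == m)]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < 0.6:
                    score = float(np.clip(rng.normal(ppi_in_score, 0.05), 0, 1))
                    edges.append((members[i], members[j], score))
    n_bg = 5 * len(symbols)
    for _ in range(n_bg):
        i, j = rng.choice(len(symbols), size=2, replace=False)
        score = float(np.clip(rng.exponential(ppi_out_score), 0, 1))
        edges.append((symbols[i], symbols[j], score))
    ppi = PPINetwork(pd.DataFrame(edges, columns=["node1", "node2", "score"]))

    truth = SyntheticTruth(
        nucleus_sample=sample,
        condition_of_nucleus=condition,
        module_of_tf=module_of_tf,
        module_of_gene=module_of_gene,
        gs_membership=membership,
        extra={"factors": factors},
    )
    return tf_matrix, gene_matrix, gene_sets, ppi, truth


def generate_importance_matrix(
    config: SyntheticConfig,
    *,
    member_fraction: float = 0.8,
    signal: float = 0.6,
    noise_scale: float = 0.01,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Synthetic nonnegative regulator-regulatee matrix with planted modules.

    Member genes receive a total importance mass ``signal`` spread over their
    module's TFs; everything else is small exponential noise. Per-gene column
    sums stay below 1, as for forest-derived explained-variance importances.
    """
    rng = np.random.default_rng(config.seed + 4)
    M = config.n_modules
    module_of_tf = _assign_modules(rng, config.n_tfs, M, member_fraction)
    module_of_gene = _assign_modules(rng, config.n_genes, M, member_fraction)
    R = rng.exponential(noise_scale, size=(config.n_tfs, config.n_genes))
    for g, m in enumerate(module_of_gene):
        if m < 0:
            continue
        tfs = np.flatnonzero(module_of_tf == m)
        w = rng.dirichlet(np.ones(len(tfs)))
        R[tfs, g] += signal * w * rng.uniform(0.7, 1.3)
    tf_names = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    gene_names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    truth = SyntheticTruth(module_of_tf=module_of_tf, module_of_gene=module_of_gene)
    return pd.DataFrame(R, index=tf_names, columns=gene_names), truth
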