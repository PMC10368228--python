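"""Per-nucleus quality metrics and filters for snATAC-seq data cleaning.

A nucleus is kept when it has abundant, TSS-enriched fragments, its
per-chromosome fragment proportions do not deviate from the cohort (free-DNA
contamination), and its fragment-size spectrum shows the expected nucleosomal
periodicity. Externally computed multiplet/doublet flags are honoured as
additional boolean filters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ConfigurationError, FragmentSet

RATIO_CAP = 1e6

DEFAULT_THRESHOLDS = {
    "min_tss_fragments": 1000,
    "min_tss_fraction": 0.075,
    "min_tss_insertion_ratio": 4.0,
    "max_chrom_deviation": 40.0,
    "periodicity_lower_pct": 1.0,
    "periodicity_upper_pct": 99.0,
}


def tss_metrics(frags: FragmentSet, tss: pd.DataFrame) -> pd.DataFrame:
    """TSS fragment counts, fractions, and insertion-rate ratios per nucleus.

    ``tss`` needs columns chrom, tss. A fragment counts towards
    ``tss_fragment_count`` when it overlaps any TSS +/- 1 kb window. The
    insertion ratio compares the per-bp Tn5 insertion rate within 25 bp of a
    TSS (51 bp window) against the rate at 1,900-2,000 bp from a TSS (both
    flanks, 202 bp total), capped at 1e6 when the far rate is zero.
    """
    if tss.empty:
        raise ConfigurationError("TSS annotation is empty")
    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in tss.groupby("chrom")}

    d = frags.data
    # fragment overlaps [tss-1000, tss+1000] iff some tss in [start-1000, end-1+1000]
    frag_hit = np.zeros(len(d), dtype=bool)
    starts = d["start"].to_numpy()
    ends = d["end"].to_numpy()
    for chrom, idx in d.groupby("chrom").indices.items():
        sites = tss_by_chrom.get(chrom)
        if sites is None:
            continue
        lo = starts[idx] - 1000
        hi = ends[idx] - 1 + 1000
        frag_hit[idx] = np.searchsorted(sites, hi, "right") > np.searchsorted(sites, lo, "left")

    ins = frags.insertion_positions()
    pos = ins["pos"].to_numpy()
    near = np.zeros(len(ins), dtype=bool)
    far = np.zeros(len(ins), dtype=bool)
    for chrom, idx in ins.groupby("chrom").indices.items():
        sites = tss_by_chrom.get(chrom)
        if sites is None:
            continue
        p = pos[idx]
        j = np.clip(np.searchsorted(sites, p), 1, len(sites))
        dist = np.minimum(np.abs(p - sites[j - 1]),
                          np.abs(p - sites[np.minimum(j, len(sites) - 1)]))
        near[idx] = dist <= 25
        far[idx] = (dist >= 1900) & (dist <= 2000)

    rows = []
    ins_bc = ins["barcode"].to_numpy()
    frag_bc = d["barcode"].to_numpy()
    for bc in frags.barcodes:
        fsel = frag_bc == bc
        isel = ins_bc == bc
        total = int(fsel.sum())
        n_hit = int(frag_hit[fsel].sum())
        near_rate = near[isel].sum() / 51.0
        far_rate = far[isel].sum() / 202.0
        if near_rate == 0 and far_rate == 0:
            ratio = 0.0
        elif far_rate == 0:
            ratio = RATIO_CAP
        else:
            ratio = min(near_rate / far_rate, RATIO_CAP)
        rows.append((bc, n_hit, n_hit / total if total else 0.0, ratio, total))
    return pd.DataFrame(
        rows,
        columns=["barcode", "tss_fragment_count", "tss_fraction",
                 "tss_insertion_ratio", "n_fragments"],
    ).set_index("barcode")


def chromosome_deviation_score(frags: FragmentSet) -> pd.Series:
    """Contamination score: per-nucleus chromosome fragment proportions are
    column-standardized across nuclei and the absolute standardized values
    summed over chromosomes. Depends only on proportions, not depth.
    Zero-SD chromosome columns contribute 0."""
    counts = pd.crosstab(frags.data["barcode"], frags.data["chrom"])
    if counts.shape[1] < 2 or counts.shape[0] < 2:
        raise ConfigurationError("need >= 2 chromosomes and >= 2 nuclei")
    prop = counts.div(counts.sum(axis=1), axis=0)
    sd = prop.std(axis=0, ddof=1)
    sd = sd.where(sd > 1e-12, np.inf)  # constant columns carry no signal
    z = (prop - prop.mean(axis=0)).div(sd, axis=1)
    return z.abs().sum(axis=1).rename("chrom_deviation_score")


def periodogram_score(sizes: np.ndarray) -> float:
    """Summed spectral power at periods 100-300 bp of the mean-subtracted
    1-bp fragment-size histogram over [1, 1000] bp."""
    hist = np.bincount(np.clip(np.asarray(sizes, dtype=int), 1, 1000),
                       minlength=1001)[1:].astype(float)
    hist -= hist.mean()
    power = np.abs(np.fft.rfft(hist)) ** 2 / len(hist)
    # frequency k/1000 cycles/bp has period 1000/k; periods in [100, 300] <=> k in [4, 10]
    return float(power[4:11].sum())


def fragment_size_spectrum(frags: FragmentSet, min_fragments: int = 100) -> pd.Series:
    """Nucleosome-periodicity score per nucleus; NaN when a nucleus has fewer
    than ``min_fragments`` fragments (such nuclei are flagged for removal)."""
    sizes = (frags.data["end"] - frags.data["start"]).to_numpy()
    bc = frags.data["barcode"].to_numpy()
    out = {}
    for barcode in frags.barcodes:
        s = sizes[bc == barcode]
        out[barcode] = periodogram_score(s) if len(s) >= min_fragments else np.nan
    return pd.Series(out, name="periodicity_score")


def periodicity_flags(
    scores: pd.Series,
    samples: pd.Series | None = None,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
) -> pd.Series:
    """True = keep. Nuclei below the lower or above the upper percentile of
    periodicity scores (within sample) fail; NaN scores fail."""
    keep = pd.Series(False, index=scores.index)
    groups = (samples.reindex(scores.index) if samples is not None
              else pd.Series("all", index=scores.index))
    for _, idx in groups.groupby(groups).groups.items():
        vals = scores.loc[idx]
        ok = vals.notna()
        if ok.sum() == 0:
            continue
        lo = np.percentile(vals[ok], lower_pct)
        hi = np.percentile(vals[ok], upper_pct)
        keep.loc[idx] = ok & (vals > lo) & (vals < hi)
    return keep.rename("pass_periodicity")


def apply_qc_filters(
    metrics: pd.DataFrame,
    thresholds: dict | None = None,
    external_flags: pd.DataFrame | None = None,
    samples: pd.Series | None = None,
) -> pd.DataFrame:
    """Combine per-filter pass flags; a nucleus passes iff every enabled
    filter passes. ``metrics`` may carry any of tss_fragment_count,
    tss_fraction, tss_insertion_ratio, chrom_deviation_score,
    pass_periodicity. Setting a threshold to None disables that filter; a
    threshold may also be a {sample: value} mapping (with ``samples`` giving
    the per-nucleus sample label), as when different samples need different
    TSS-fraction cutoffs. ``external_flags`` columns (e.g. not_multiplet,
    not_doublet; True = keep) are conjoined as additional filters.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    def _resolve(key):
        t = th[key]
        if isinstance(t, dict):
            if samples is None:
                raise ConfigurationError(
                    f"per-sample threshold for {key} needs a samples series")
            mapped = samples.reindex(metrics.index).map(t)
            if mapped.isna().any():
                raise ConfigurationError(f"missing per-sample threshold for {key}")
            return mapped
        return t

    flags = pd.DataFrame(index=metrics.index)
    checks = [
        ("min_tss_fragments", "tss_fragment_count",
         lambda v, t: v >= t, "pass_tss_count"),
        ("min_tss_fraction", "tss_fraction",
         lambda v, t: v >= t, "pass_tss_fraction"),
        ("min_tss_insertion_ratio", "tss_insertion_ratio",
         lambda v, t: v >= t, "pass_tss_ratio"),
        ("max_chrom_deviation", "chrom_deviation_score",
         lambda v, t: v < t, "pass_chrom_deviation"),
    ]
    for key, col, fn, name in checks:
        if th.get(key) is None:
            continue
        if col not in metrics.columns:
            raise ConfigurationError(f"filter {key} enabled but column {col} missing")
        flags[name] = fn(metrics[col], _resolve(key))
    if "pass_periodicity" in metrics.columns:
        flags["pass_periodicity"] = metrics["pass_periodicity"].astype(bool)
    if external_flags is not None:
        for col in external_flags.columns:
            flags[col] = external_flags.reindex(metrics.index)[col].fillna(False).astype(bool)
    flags["pass_all"] = flags.all(axis=1) if flags.shape[1] else True
    return flags
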