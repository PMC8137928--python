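"""Sliding windows, z-standardisation, dual-criterion outliers, region
merging and recombination proxies (windowed LD r2, intronic GC).

Windows are 0-based half-open, 200 kb wide with 50 kb steps by default;
a 1-based SNP at position p belongs to window [start, end) iff
p - 1 is in [start, end). Window-level outliers use the dual rule: the
window mean of the statistic AND the proportion of SNP-level outliers must
both reach the 95th percentile of their genome-wide distributions, computed
separately for autosomes and the Z chromosome. The window-mean-F_ST variant
instead flags ZF_ST > 4. Adjacent flagged windows not more than 200 kb
apart merge into outlier regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "make_windows",
    "summarise_in_windows",
    "zscore_by_class",
    "dual_criterion_outliers",
    "zfst_outliers",
    "merge_regions",
    "ld_windows",
    "intronic_gc_windows",
    "correlate_windows",
]

DEFAULT_SIZE = 200_000
DEFAULT_STEP = 50_000
DEFAULT_MIN_SNPS = 10


def make_windows(chrom_lengths, size=DEFAULT_SIZE, step=DEFAULT_STEP,
                 chrom_class=None):
    """Sliding-window skeleton: starts 0, step, 2*step, ... while start < length."""
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    rows = []
    classes = dict(chrom_class or {})
    for c, length in chrom_lengths.items():
        start = 0
        while start < length:
            rows.append(
                dict(chrom=c, start=start, end=min(start + size, length),
                     chrom_class=classes.get(c, "autosome"))
            )
            start += step
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "chrom_class"])


def summarise_in_windows(snp_stats, windows, snp_threshold,
                         min_snps=DEFAULT_MIN_SNPS, stat_col="stat",
                         threshold_op=">"):
    """Summarise a per-SNP statistic into windows.

    ``snp_stats``: DataFrame (chrom, pos, <stat_col>) sorted by position
    within chromosome. Adds n_snps, mean_stat, prop_outlier_snps (share of
    SNPs beyond ``snp_threshold`` under ``threshold_op``) and an
    ``eligible`` flag (n_snps >= min_snps) to a copy of ``windows``.
    """
    out = windows.copy()
    out["n_snps"] = 0
    out["mean_stat"] = np.nan
    out["prop_outlier_snps"] = np.nan
    for c, wsub in out.groupby("chrom", sort=False):
        ssub = snp_stats[snp_stats["chrom"] == c]
        pos = ssub["pos"].to_numpy()
        if len(pos) > 1 and not (np.diff(pos) > 0).all():
            raise ValueError(f"SNP stats not sorted by position on {c}")
        vals = ssub[stat_col].to_numpy(dtype=float)
        if threshold_op == ">":
            flags = (vals > snp_threshold).astype(float)
        elif threshold_op == ">=":
            flags = (vals >= snp_threshold).astype(float)
        else:
            raise ValueError("threshold_op must be '>' or '>='")
        cum_v = np.concatenate([[0.0], np.cumsum(vals)])
        cum_f = np.concatenate([[0.0], np.cumsum(flags)])
        p0 = pos - 1  # interval coordinate
        lo = np.searchsorted(p0, wsub["start"].to_numpy(), side="left")
        hi = np.searchsorted(p0, wsub["end"].to_numpy(), side="left")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (cum_v[hi] - cum_v[lo]) / np.maximum(n, 1), np.nan)
            prop = np.where(n > 0, (cum_f[hi] - cum_f[lo]) / np.maximum(n, 1), np.nan)
        out.loc[wsub.index, "n_snps"] = n
        out.loc[wsub.index, "mean_stat"] = mean
        out.loc[wsub.index, "prop_outlier_snps"] = prop
    out["eligible"] = out["n_snps"] >= min_snps
    return out


def zscore_by_class(values, chrom_class):
    """z = (v - mean) / sd within each chromosome class (population SD)."""
    values = np.asarray(values, dtype=float)
    classes = np.asarray(chrom_class, dtype=object)
    out = np.empty_like(values)
    for cls in pd.unique(classes):
        sel = classes == cls
        v = values[sel]
        if np.isfinite(v).sum() < 2:
            raise ValueError(f"need >= 2 values in class {cls!r}")
        m, sd = np.nanmean(v), np.nanstd(v)
        if sd == 0:
            raise ValueError(f"zero standard deviation in class {cls!r}")
        out[sel] = (v - m) / sd
    return out


def dual_criterion_outliers(window_table, percentile=95.0):
    """Dual-criterion window outlier flags.

    A window is an outlier iff its mean statistic AND its proportion of
    SNP-level outliers both reach the ``percentile`` of the genome-wide
    distribution of eligible windows, computed within its chromosome class
    (type-7 linear interpolation; >= comparison). Degenerate classes whose
    values have zero spread yield no flags. Returns a boolean Series
    aligned to ``window_table``.
    """
    wt = window_table
    flags = pd.Series(False, index=wt.index)
    elig = wt[wt["eligible"]]
    for cls, sub in elig.groupby("chrom_class"):
        if len(sub) < 20:
            import warnings

            warnings.warn(
                f"only {len(sub)} eligible windows in class {cls!r}; "
                "percentile thresholds unstable",
                stacklevel=2,
            )
        mean_v = sub["mean_stat"].to_numpy(dtype=float)
        prop_v = sub["prop_outlier_snps"].to_numpy(dtype=float)
        finite_m = mean_v[np.isfinite(mean_v)]
        finite_p = prop_v[np.isfinite(prop_v)]
        if np.ptp(finite_m) == 0 and np.ptp(finite_p) == 0:
            continue  # all windows identical: percentile = value, suppress flags
        thr_mean = np.nanpercentile(mean_v, percentile)
        thr_prop = np.nanpercentile(prop_v, percentile)
        hit = (mean_v >= thr_mean) & (prop_v >= thr_prop)
        flags.loc[sub.index[hit]] = True
    return flags


def zfst_outliers(window_table, z_threshold=4.0):
    """Single-rule ZF_ST variant: flag windows with zfst > threshold."""
    z = zscore_by_class(
        window_table["mean_stat"].to_numpy(dtype=float),
        window_table["chrom_class"].to_numpy(dtype=object),
    )
    wt = window_table.copy()
    wt["zfst"] = z
    wt["outlier"] = (z > z_threshold) & wt["eligible"]
    return wt


def merge_regions(window_table, flags=None, max_gap=200_000):
    """Merge flagged windows <= max_gap apart into outlier regions.

    Overlapping sliding windows (negative gap) always merge; a gap of
    exactly ``max_gap`` still merges ("not more than 200 kb apart").
    Regions are non-overlapping, sorted, and carry the merged window count
    and the peak window mean. Idempotent on its own output.
    """
    wt = window_table if flags is None else window_table[np.asarray(flags, dtype=bool)]
    if "outlier" in wt.columns and flags is None:
        wt = wt[wt["outlier"].astype(bool)]
    wt = wt.sort_values(["chrom", "start"])
    regions = []
    for _, row in wt.iterrows():
        if (
            regions
            and regions[-1]["chrom"] == row["chrom"]
            and row["start"] - regions[-1]["end"] <= max_gap
        ):
            r = regions[-1]
            r["end"] = max(r["end"], int(row["end"]))
            r["n_windows"] += 1
            r["peak_stat"] = max(r["peak_stat"], float(row.get("mean_stat", np.nan)))
        else:
            regions.append(
                dict(chrom=row["chrom"], start=int(row["start"]), end=int(row["end"]),
                     n_windows=1, peak_stat=float(row.get("mean_stat", np.nan)))
            )
    return pd.DataFrame(
        regions, columns=["chrom", "start", "end", "n_windows", "peak_stat"]
    )


def ld_windows(panel, sample_idx=None, window=DEFAULT_SIZE, max_dist=DEFAULT_SIZE):
    """Mean pairwise LD r2 per non-sliding window for one population.

    r2 is the squared Pearson correlation of dosages over all SNP pairs
    within the same window and at most ``max_dist`` bp apart; monomorphic
    SNPs are skipped. Returns a DataFrame (chrom, start, end, n_pairs,
    mean_r2).
    """
    dos = panel.dosages().astype(float)
    if sample_idx is not None:
        dos = dos[:, np.asarray(sample_idx, dtype=np.intp)]
    rows = []
    for c in panel.chromosomes():
        on = np.flatnonzero(panel.sites_on(c))
        pos = panel.pos[on]
        w_idx = (pos - 1) // window
        for w in np.unique(w_idx):
            sel = on[w_idx == w]
            psel = pos[w_idx == w]
            sub = dos[sel]
            poly = sub.std(axis=1) > 0
            sub, psel = sub[poly], psel[poly]
            if len(psel) < 2:
                continue
            R = np.corrcoef(sub)
            iu = np.triu_indices(len(psel), k=1)
            dist = np.abs(psel[iu[0]] - psel[iu[1]])
            r2 = R[iu] ** 2
            keep = dist <= max_dist
            if not keep.any():
                continue
            rows.append(
                dict(chrom=c, start=int(w * window), end=int((w + 1) * window),
                     n_pairs=int(keep.sum()), mean_r2=float(r2[keep].mean()))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_pairs", "mean_r2"])


def intronic_gc_windows(fasta, genes, window=DEFAULT_SIZE):
    """Mean intronic GC per non-sliding window.

    ``fasta`` is a path or a pyfaidx.Fasta; per-intron GC = (G+C)/(A+C+G+T)
    ignoring N; each intron is assigned to the window containing its
    midpoint; the window value is the unweighted mean over introns.
    """
    import pyfaidx

    fa = fasta if isinstance(fasta, pyfaidx.Fasta) else pyfaidx.Fasta(str(fasta))
    acc = {}
    for _, g in genes.iterrows():
        seq_len = len(fa[g["chrom"]])
        for (s, e) in g["introns"]:
            if e > seq_len:
                raise ValueError(
                    f"intron [{s},{e}) of gene {g['gene_id']} beyond end of "
                    f"{g['chrom']} (length {seq_len})"
                )
            seq = str(fa[g["chrom"]][s:e]).upper()
            counts = {b: seq.count(b) for b in "ACGT"}
            denom = sum(counts.values())
            if denom == 0:
                continue
            gc = (counts["G"] + counts["C"]) / denom
            mid = (s + e) // 2
            key = (g["chrom"], mid // window)
            acc.setdefault(key, []).append(gc)
    rows = [
        dict(chrom=c, start=int(w * window), end=int((w + 1) * window),
             n_introns=len(v), mean_gc=float(np.mean(v)))
        for (c, w), v in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_introns", "mean_gc"])


def correlate_windows(a, b):
    """Pearson r and two-sided p between two matched window-value vectors.

    Only complete cases (both values finite) enter; fewer than 3 complete
    cases is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("window value vectors must be matched")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete cases")
    r, p = sps.pearsonr(a[ok], b[ok])
    return float(r), float(p)
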