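"""Haplotype-homozygosity selection statistics: EHH, EHHS, iES, Rsb, nSL, XP-nSL.

All statistics are computed from scratch on phased 0/1 haplotype matrices.

* EHH(x): probability that two random haplotypes carrying the core allele
  are identical over the whole interval from the core SNP out to x.
* EHHS(x): site-specific analogue over ALL haplotypes — the probability two
  random haplotypes are identical over the interval *and* at the core —
  normalised to 1 at the core (Tang-style normalisation, the rehh default).
* iES: trapezoidal integral of the two-sided EHHS curve over physical
  distance, truncated where EHHS drops below a cutoff (default 0.05), at
  inter-SNP gaps larger than ``max_gap`` (default 200 kb), or at the
  chromosome edge.
* Rsb: ln(iES_pop1 / iES_pop2) per SNP, standardised by subtracting the
  median and dividing by the SD, separately for autosomes and the Z
  chromosome. With (urban, rural) argument order, positive values mean
  haplotype homozygosity extends further in the urban population; SNPs with
  Rsb >= 4 are outliers.
* nSL lengths: mean over haplotype pairs of the number of consecutive SNPs
  in the maximal interval containing the core over which the pair is
  identical (0 when the pair differs at the core; truncated at chromosome
  edges). XP-nSL is the standardised ln-ratio of whole-population mean
  pairwise lengths (mean/SD, per chromosome class); outliers at > 2.

SNPs with minor-allele frequency below ``maf_min`` (default 0.05) in *both*
populations are excluded as scan cores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ehh",
    "ehhs",
    "integrate_ies",
    "ies_scan",
    "rsb_scan",
    "nsl_lengths",
    "sl_scan",
    "xpnsl_scan",
    "ScanResult",
]

DEFAULT_CUTOFF = 0.05
DEFAULT_MAX_GAP = 200_000
DEFAULT_MAF = 0.05


# ---------------------------------------------------------------------------
# EHH / EHHS curves
# ---------------------------------------------------------------------------

def _homozygosity(ids):
    """Sum over identity classes of c*(c-1) / (n*(n-1))."""
    n = len(ids)
    counts = np.bincount(ids)
    return float((counts * (counts - 1)).sum()) / (n * (n - 1))


def _extend(haps, start_ids, core, direction, positions, cutoff, max_gap, h0):
    """Walk outward from the core, splitting identity classes SNP by SNP."""
    S = haps.shape[1]
    ids = np.unique(start_ids, return_inverse=True)[1]
    pos_out = [int(positions[core])]
    val_out = [1.0]
    j = core
    while True:
        j_next = j + direction
        if j_next < 0 or j_next >= S:
            break
        if abs(int(positions[j_next]) - int(positions[j])) > max_gap:
            break
        ids = np.unique(ids * 2 + haps[:, j_next], return_inverse=True)[1]
        val = _homozygosity(ids) / h0 if h0 > 0 else 0.0
        if val < cutoff:
            break
        pos_out.append(int(positions[j_next]))
        val_out.append(val)
        j = j_next
    return np.array(pos_out, dtype=np.int64), np.array(val_out)


def ehh(haps, positions, core, core_allele, direction,
        cutoff=0.0, max_gap=DEFAULT_MAX_GAP):
    """EHH decay curve conditioned on carrying ``core_allele`` at the core.

    ``haps`` is (n_haplotypes, n_sites) for one chromosome; ``direction`` is
    +1 (rightwards) or -1. Returns (positions, values) arrays starting at
    the core with EHH = 1; the curve is monotone non-increasing.
    """
    carriers = haps[:, core] == core_allele
    if carriers.sum() < 2:
        raise ValueError(
            f"fewer than 2 haplotypes carry allele {core_allele} at core index {core}"
        )
    sub = haps[carriers]
    start = np.zeros(sub.shape[0], dtype=np.int64)  # all identical on empty interval
    return _extend(sub, start, core, direction, positions, cutoff, max_gap, h0=1.0)


def ehhs(haps, positions, core, direction, cutoff=0.0, max_gap=DEFAULT_MAX_GAP):
    """Site-specific EHHS decay curve over all haplotypes.

    h(x) is the probability two random haplotypes are identical over the
    interval from the core to x and identical at the core; the curve is
    h(x)/h(core). A monomorphic core reduces to plain unconditioned
    homozygosity (still defined).
    """
    if haps.shape[0] < 2:
        raise ValueError("need >= 2 haplotypes")
    start = haps[:, core].astype(np.int64)
    h0 = _homozygosity(np.unique(start, return_inverse=True)[1])
    return _extend(haps, start, core, direction, positions, cutoff, max_gap, h0=h0)


def integrate_ies(left, right, cutoff=DEFAULT_CUTOFF):
    """Trapezoidal iES (bp) from left+right (positions, values) curves.

    Curves are assumed already truncated at the cutoff/gap rule by the curve
    builders; points below the cutoff, if present, are discarded here too.
    Returns the sum of the left and right integrals over physical distance.
    """
    total = 0.0
    for pos, val in (left, right):
        below = np.flatnonzero(val < cutoff)
        if len(below):
            pos, val = pos[: below[0]], val[: below[0]]
        if len(pos) < 2:
            continue
        d = np.abs(pos - pos[0]).astype(float)
        total += float(np.trapezoid(val, d))
    return total


def _pair_mismatch_bounds(haps):
    """Per-pair shared-segment bounds at every SNP, for the fast iES scan.

    For each haplotype pair and core index c: ``alive[p, c]`` — the pair is
    identical at c; ``rnext[p, c]`` — index of the first mismatch strictly
    right of c (S if none); ``lprev[p, c]`` — index of the last mismatch
    strictly left of c (-1 if none). A pair is identical over [c..x] iff it
    is alive at c and rnext > x (rightwards; symmetrically leftwards) —
    the same identity relation the cluster-splitting curves use.
    """
    n, S = haps.shape
    n_pairs = n * (n - 1) // 2
    alive = np.empty((n_pairs, S), dtype=bool)
    rnext = np.empty((n_pairs, S), dtype=np.int32)
    lprev = np.empty((n_pairs, S), dtype=np.int32)
    xs = np.arange(S)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            diff = np.flatnonzero(haps[i] != haps[j])
            idx = np.searchsorted(diff, xs, side="right")  # mismatches <= x
            idx_l = np.searchsorted(diff, xs, side="left")  # mismatches < x
            alive[k] = idx == idx_l  # no mismatch at x itself
            rnext[k] = np.where(idx < len(diff), diff[np.minimum(idx, len(diff) - 1)], S) if len(diff) else S
            lprev[k] = np.where(idx_l > 0, diff[np.maximum(idx_l - 1, 0)], -1) if len(diff) else -1
            k += 1
    return alive, rnext, lprev


def ies_scan(haps, positions, cores=None, cutoff=DEFAULT_CUTOFF,
             max_gap=DEFAULT_MAX_GAP):
    """iES for every requested core SNP on one chromosome. NaN if undefined.

    Equivalent to integrating the :func:`ehhs` curves in both directions,
    but computed from per-pair mismatch bounds so the whole-chromosome scan
    is a single O(pairs * sites) pass.
    """
    n, S = haps.shape
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    if cores is None:
        cores = np.arange(S)
    alive, rnext, lprev = _pair_mismatch_bounds(haps)
    pos = np.asarray(positions, dtype=np.int64)
    # first over-gap break at or right of each index / at or left of it
    big = np.flatnonzero(np.diff(pos) > max_gap)  # gap between j and j+1
    next_gap = np.full(S, S - 1, dtype=np.int64)
    for g in big[::-1]:
        next_gap[: g + 1] = np.minimum(next_gap[: g + 1], g)
    prev_gap = np.zeros(S, dtype=np.int64)
    for g in big:
        prev_gap[g + 1 :] = np.maximum(prev_gap[g + 1 :], g + 1)
    out = np.full(S, np.nan)
    for c in cores:
        al = alive[:, c]
        a = int(al.sum())
        if a == 0:
            continue  # no identical pair at the core: EHHS normalisation undefined
        total = 0.0
        # rightwards: value at x = #{alive pairs with rnext > x} / a
        limit_r = next_gap[c]
        xs = np.arange(c, limit_r + 1)
        r_sorted = np.sort(rnext[al, c])
        vals = (a - np.searchsorted(r_sorted, xs, side="right")) / a
        below = np.flatnonzero(vals < cutoff)
        if len(below):
            xs, vals = xs[: below[0]], vals[: below[0]]
        if len(xs) >= 2:
            total += float(np.trapezoid(vals, (pos[xs] - pos[c]).astype(float)))
        # leftwards: value at x = #{alive pairs with lprev < x} / a
        limit_l = prev_gap[c]
        xs = np.arange(c, limit_l - 1, -1)
        l_sorted = np.sort(lprev[al, c])
        vals = np.searchsorted(l_sorted, xs, side="left") / a
        below = np.flatnonzero(vals < cutoff)
        if len(below):
            xs, vals = xs[: below[0]], vals[: below[0]]
        if len(xs) >= 2:
            total += float(np.trapezoid(vals, (pos[c] - pos[xs]).astype(float)))
        out[c] = total
    return out


# ---------------------------------------------------------------------------
# nSL pairwise lengths
# ---------------------------------------------------------------------------

def _sl_pair_lengths(h1, h2):
    """Per-core shared-interval lengths (SNP units) for one haplotype pair."""
    S = len(h1)
    diff = np.flatnonzero(h1 != h2)
    out = np.zeros(S)
    bounds = np.concatenate([[-1], diff, [S]])
    lens = np.diff(bounds) - 1
    mask = np.ones(S, dtype=bool)
    mask[diff] = False
    out[mask] = np.repeat(lens, lens)
    return out


def sl_scan(haps):
    """Whole-population mean pairwise shared length at every SNP (one chrom)."""
    n, S = haps.shape
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    total = np.zeros(S)
    for i in range(n):
        for j in range(i + 1, n):
            total += _sl_pair_lengths(haps[i], haps[j])
    return total / (n * (n - 1) / 2)


def nsl_lengths(haps, core):
    """Mean pairwise shared lengths at one core, split by carrier set.

    Returns a dict with mean L over pairs within ancestral (allele 0)
    carriers, within derived (allele 1) carriers, and over the whole
    population; entries are NaN when fewer than 2 haplotypes qualify.
    """
    out = {}
    for label, rows in (
        ("ancestral", np.flatnonzero(haps[:, core] == 0)),
        ("derived", np.flatnonzero(haps[:, core] == 1)),
        ("all", np.arange(haps.shape[0])),
    ):
        if len(rows) < 2:
            out[label] = float("nan")
            continue
        vals = [
            _sl_pair_lengths(haps[a], haps[b])[core]
            for k, a in enumerate(rows)
            for b in rows[k + 1:]
        ]
        out[label] = float(np.mean(vals))
    return out


# ---------------------------------------------------------------------------
# cross-population scans
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    """Per-SNP cross-population scan output (defined SNPs only)."""

    chrom: np.ndarray
    pos: np.ndarray
    stat_urban: np.ndarray
    stat_rural: np.ndarray
    ln_ratio: np.ndarray
    score: np.ndarray       # standardised
    outlier: np.ndarray
    statistic: str

    def to_frame(self):
        a = "ies" if self.statistic == "rsb" else "sl"
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                f"{a}_urban": self.stat_urban,
                f"{a}_rural": self.stat_rural,
                "ln_ratio": self.ln_ratio,
                self.statistic: self.score,
                "outlier": self.outlier,
            }
        )


def _check_same_map(pu, pr):
    if pu.n_sites != pr.n_sites or not (
        (pu.pos == pr.pos).all() and (pu.chrom == pr.chrom).all()
    ):
        raise ValueError("urban and rural panels must share an identical site map")


def _core_mask(pu, pr, maf_min):
    fu = pu.alt_freq()
    fr = pr.alt_freq()
    maf_u = np.minimum(fu, 1 - fu)
    maf_r = np.minimum(fr, 1 - fr)
    return (maf_u >= maf_min) | (maf_r >= maf_min)


def _standardise(values, classes, center):
    """Per-chromosome-class standardisation; degenerate SD -> scores 0."""
    out = np.empty_like(values, dtype=float)
    for cls in np.unique(classes):
        sel = classes == cls
        v = values[sel]
        mid = np.median(v) if center == "median" else np.mean(v)
        sd = np.std(v)
        out[sel] = 0.0 if sd == 0 else (v - mid) / sd
    return out


def _cross_pop_scan(panel_urban, panel_rural, per_chrom_stat, maf_min):
    _check_same_map(panel_urban, panel_rural)
    mask = _core_mask(panel_urban, panel_rural, maf_min)
    chroms, poss, su, sr = [], [], [], []
    for c in panel_urban.chromosomes():
        on = panel_urban.sites_on(c)
        cores = np.flatnonzero(mask[on])
        if len(cores) == 0:
            continue
        hap_u = panel_urban.haplotypes[on].T
        hap_r = panel_rural.haplotypes[on].T
        pos = panel_urban.pos[on]
        stat_u = per_chrom_stat(hap_u, pos, cores)
        stat_r = per_chrom_stat(hap_r, pos, cores)
        chroms.append(np.repeat(c, len(cores)))
        poss.append(pos[cores])
        su.append(stat_u[cores])
        sr.append(stat_r[cores])
    chrom = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    pos = np.concatenate(poss) if poss else np.empty(0, dtype=np.int64)
    stat_u = np.concatenate(su) if su else np.empty(0)
    stat_r = np.concatenate(sr) if sr else np.empty(0)
    valid = np.isfinite(stat_u) & np.isfinite(stat_r) & (stat_u > 0) & (stat_r > 0)
    classes = np.array(
        [panel_urban.class_of(c) for c in chrom[valid]], dtype=object
    )
    # difference of logs (not log of ratio) so argument swap negates exactly
    lnr = np.log(stat_u[valid]) - np.log(stat_r[valid])
    return chrom[valid], pos[valid], stat_u[valid], stat_r[valid], lnr, classes


def rsb_scan(panel_urban, panel_rural, maf_min=DEFAULT_MAF,
             cutoff=DEFAULT_CUTOFF, max_gap=DEFAULT_MAX_GAP, threshold=4.0):
    """Rsb scan: standardised ln(iES_urban / iES_rural) per SNP.

    Positive scores mean extended haplotype homozygosity reaches further in
    the urban population (selection in urban); standardisation is by
    median/SD separately for autosomes and the Z chromosome; outliers at
    Rsb >= threshold (default 4).
    """
    stat = lambda h, p, cores: ies_scan(h, p, cores, cutoff=cutoff, max_gap=max_gap)
    chrom, pos, su, sr, lnr, classes = _cross_pop_scan(
        panel_urban, panel_rural, stat, maf_min
    )
    score = _standardise(lnr, classes, center="median")
    return ScanResult(chrom, pos, su, sr, lnr, score, score >= threshold, "rsb")


def xpnsl_scan(panel_urban, panel_rural, maf_min=DEFAULT_MAF, threshold=2.0):
    """XP-nSL scan: standardised ln(SL_urban / SL_rural) per SNP.

    SL is the whole-population mean pairwise shared haplotype length in SNP
    units; standardisation is by mean/SD separately per chromosome class;
    outliers at score > threshold (default 2). Positive scores indicate
    selection in the urban population.
    """
    stat = lambda h, p, cores: sl_scan(h)
    chrom, pos, su, sr, lnr, classes = _cross_pop_scan(
        panel_urban, panel_rural, stat, maf_min
    )
    score = _standardise(lnr, classes, center="mean")
    return ScanResult(chrom, pos, su, sr, lnr, score, score > threshold, "xpnsl")
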