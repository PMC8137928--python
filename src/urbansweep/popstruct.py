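"""Diversity, differentiation and population-structure statistics.

Expected heterozygosity, Weir & Cockerham (1984) pairwise F_ST with a
permutation test on a ~50 kb-thinned SNP set, VIF-based LD pruning,
dosage PCA, Mantel tests and isolation-by-distance split by habitat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import haversine_distances

__all__ = [
    "expected_heterozygosity",
    "wc_fst",
    "fst_permutation_test",
    "ld_prune",
    "genotype_pca",
    "mantel_test",
    "ibd_by_habitat",
    "haversine_km",
    "FstResult",
    "MantelResult",
]

EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def expected_heterozygosity(panel, samples, locality, habitat):
    """Mean expected heterozygosity 2p(1-p) over all SNPs for one population."""
    idx = panel.sample_index(samples.members(locality, habitat))
    p = panel.alt_freq(idx)
    return float(np.mean(2.0 * p * (1.0 - p)))


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstResult:
    theta: np.ndarray          # per-SNP theta-hat (NaN where undefined)
    pair_mean: float           # mean over defined SNPs of max(theta, 0)
    n_monomorphic: int         # SNPs monomorphic across both pops, excluded
    perm_p: float | None = None


def _wc_components(dosA, dosB):
    """Weir & Cockerham (1984) a, b, c variance components, two populations.

    Vectorised over SNPs; inputs are (n_snps, n_ind) ALT-dosage matrices.
    """
    nA = dosA.shape[1]
    nB = dosB.shape[1]
    r = 2
    pA = dosA.mean(axis=1) / 2.0
    pB = dosB.mean(axis=1) / 2.0
    hA = (dosA == 1).mean(axis=1)
    hB = (dosB == 1).mean(axis=1)
    n_bar = (nA + nB) / r
    n_c = (r * n_bar - (nA**2 + nB**2) / (r * n_bar)) / (r - 1)
    p_bar = (nA * pA + nB * pB) / (r * n_bar)
    s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (nA * hA + nB * hB) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def wc_fst(panel, samples, popA, popB, sample_idx=None):
    """Per-SNP Weir-Cockerham theta-hat between two populations.

    ``popA``/``popB`` are (locality, habitat) tuples, or ``sample_idx`` can
    supply two explicit index arrays directly. SNPs monomorphic across both
    populations have undefined theta (NaN) and are excluded from
    ``pair_mean``, which averages max(theta, 0) per the convention of
    zeroing negative estimates before averaging.
    """
    if sample_idx is None:
        idxA = panel.sample_index(samples.members(*popA))
        idxB = panel.sample_index(samples.members(*popB))
    else:
        idxA, idxB = (np.asarray(i, dtype=np.intp) for i in sample_idx)
    if len(idxA) < 2 or len(idxB) < 2:
        raise ValueError("need >= 2 diploids per population")
    dos = panel.dosages()
    a, b, c = _wc_components(dos[:, idxA], dos[:, idxB])
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    defined = ~np.isnan(theta)
    n_mono = int((~defined).sum())
    pair_mean = float(np.maximum(theta[defined], 0.0).mean()) if defined.any() else float("nan")
    return FstResult(theta=theta, pair_mean=pair_mean, n_monomorphic=n_mono)


def thin_snps(panel, bin_bp=50_000):
    """Index of the first SNP in each ``bin_bp`` bin per chromosome.

    Bins are anchored at position 1 of each chromosome.
    """
    keep = []
    for c in panel.chromosomes():
        idx = np.flatnonzero(panel.sites_on(c))
        bins = (panel.pos[idx] - 1) // bin_bp
        _, first = np.unique(bins, return_index=True)
        keep.extend(idx[first])
    return np.array(sorted(keep), dtype=np.intp)


def fst_permutation_test(panel, samples, popA, popB, n_perm=999, seed=0,
                         thin_bp=50_000):
    """Permutation P-value for pairwise F_ST on a ~50 kb-thinned SNP set.

    Individuals are permuted between the two populations preserving sizes;
    the statistic is the clamped pair mean; p = (1 + #{perm >= obs}) /
    (n_perm + 1). Deterministic under the seed.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    idxA = panel.sample_index(samples.members(*popA))
    idxB = panel.sample_index(samples.members(*popB))
    if len(idxA) + len(idxB) < 4:
        raise ValueError("need >= 4 samples in total")
    thin = thin_snps(panel, thin_bp)
    sub = panel.take_sites(thin)
    obs = wc_fst(sub, samples, popA, popB, sample_idx=(idxA, idxB)).pair_mean
    rng = np.random.default_rng(seed)
    pool = np.concatenate([idxA, idxB])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        pa, pb = perm[: len(idxA)], perm[len(idxA):]
        stat = wc_fst(sub, samples, popA, popB, sample_idx=(pa, pb)).pair_mean
        if stat >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    res = wc_fst(sub, samples, popA, popB, sample_idx=(idxA, idxB))
    res.perm_p = float(p)
    return res


# ---------------------------------------------------------------------------
# LD pruning (VIF)
# ---------------------------------------------------------------------------

def ld_prune(panel, window_snps=50, step_snps=5, vif_threshold=2.0):
    """Variance-inflation-factor LD pruning, plink ``--indep`` style.

    Within each window of ``window_snps`` SNPs (advancing ``step_snps``),
    the SNP with the highest VIF is removed iteratively until all VIFs fall
    below the threshold; VIF_i = 1/(1 - R^2_i) from regressing dosage i on
    the other SNPs in the window, equal to the i-th diagonal entry of the
    inverse correlation matrix. Monomorphic SNPs carry no information and
    are always retained. Deterministic (no RNG). Returns the retained SNP
    index array.
    """
    dos = panel.dosages().astype(float)
    removed = np.zeros(panel.n_sites, dtype=bool)
    for c in panel.chromosomes():
        idx = np.flatnonzero(panel.sites_on(c))
        start = 0
        while start < len(idx):
            window = idx[start : start + window_snps]
            _prune_window(dos, window, removed, vif_threshold)
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return np.flatnonzero(~removed)


def _prune_window(dos, window, removed, threshold, ridge=1e-8):
    active = [j for j in window if not removed[j] and dos[j].std() > 0]
    while len(active) > 1:
        X = dos[active]
        R = np.corrcoef(X)
        R[np.diag_indices_from(R)] += ridge
        vif = np.diag(np.linalg.inv(R))
        worst = int(np.argmax(vif))
        if vif[worst] < threshold:
            break
        removed[active[worst]] = True
        active.pop(worst)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def genotype_pca(panel, snp_subset=None, n_components=10):
    """PCA of centred, HWE-scaled genotype dosages.

    Dosages are centred per SNP and scaled by sqrt(p(1-p)); zero-variance
    SNPs are dropped with a warning. Each axis's sign is fixed by making its
    largest-magnitude SNP loading positive. Returns (scores, pve) with
    scores shape (n_samples, k).
    """
    dos = panel.dosages().astype(float)
    if snp_subset is not None:
        dos = dos[np.asarray(snp_subset, dtype=np.intp)]
    p = dos.mean(axis=1) / 2.0
    var_ok = (dos.std(axis=1) > 0) & (p > 0) & (p < 1)
    if not var_ok.all():
        warnings.warn(f"dropping {int((~var_ok).sum())} zero-variance SNPs from PCA",
                      stacklevel=2)
    dos = dos[var_ok]
    p = p[var_ok]
    if dos.shape[0] == 0 or dos.shape[1] < 2:
        raise ValueError("need >= 1 polymorphic SNP and >= 2 samples")
    X = (dos - 2 * p[:, None]) / np.sqrt(p * (1 - p))[:, None]
    X = X.T  # samples x snps
    U, s, Vt = np.linalg.svd(X - X.mean(axis=0), full_matrices=False)
    k = min(n_components, len(s))
    for a in range(k):
        lead = np.argmax(np.abs(Vt[a]))
        if Vt[a, lead] < 0:
            Vt[a] = -Vt[a]
            U[:, a] = -U[:, a]
    scores = U[:, :k] * s[:k]
    pve = (s**2) / (s**2).sum()
    return scores, pve[:k]


# ---------------------------------------------------------------------------
# Mantel / IBD
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def _check_dist(m):
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(m), 0):
        raise ValueError("distance matrix must have a zero diagonal")
    return m


def mantel_test(dist_a, dist_b, n_perm=999, seed=0, alternative="two-sided"):
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the upper triangles; p comes from joint
    row/column permutations of the second matrix, with the (b+1)/(n+1)
    estimator. ``alternative``: "two-sided" (default) or "greater".
    """
    A = _check_dist(dist_a)
    B = _check_dist(dist_b)
    if A.shape != B.shape:
        raise ValueError("matrices must have matching dimensions")
    iu = np.triu_indices(A.shape[0], k=1)
    x = A[iu]
    if x.std() == 0 or B[iu].std() == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")

    def corr(m):
        y = m[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(B[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    return MantelResult(r=r_obs, p=(1 + count) / (n_perm + 1), n_perm=n_perm)


def haversine_km(sites):
    """Great-circle distance matrix (km) from a site table with lat/lon."""
    coords = np.radians(sites[["latitude", "longitude"]].to_numpy(dtype=float))
    return haversine_distances(coords) * EARTH_RADIUS_KM


def ibd_by_habitat(fst_df, sites, n_perm=999, seed=0):
    """Isolation by distance tested separately within each habitat.

    ``fst_df`` is a square DataFrame of pairwise F_ST indexed and columned
    by "locality_habitat" labels; ``sites`` the site table with coordinates.
    Returns {habitat: MantelResult}. Requires >= 4 populations per habitat.
    """
    out = {}
    for hab in ("urban", "rural"):
        labels = [l for l in fst_df.index if l.endswith(f"_{hab}")]
        if len(labels) < 4:
            raise ValueError(f"need >= 4 {hab} populations for IBD")
        sub = fst_df.loc[labels, labels].to_numpy(dtype=float)
        np.fill_diagonal(sub, 0.0)
        srows = []
        for l in labels:
            loc = l.rsplit("_", 1)[0]
            row = sites[(sites["locality"] == loc) & (sites["habitat"] == hab)]
            if row.empty:
                raise KeyError(f"no site coordinates for {l}")
            srows.append(row.iloc[0])
        geo = haversine_km(pd.DataFrame(srows))
        out[hab] = mantel_test(geo, sub, n_perm=n_perm, seed=seed,
                               alternative="greater")
    return out
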