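"""Habitat x locality decomposition, allele-frequency shifts, gene-region
overlap, the cross-population gene-sharing resampling null, and
hypergeometric overrepresentation.

The decomposition fits, per candidate SNP (dosage 0/1/2) or per PC axis,
the two-factor crossed model habitat + locality + habitat:locality with
type-II sums of squares, and reports partial eta^2 = SS_term / (SS_term +
SS_residual) per term. A habitat effect exceeding the interaction effect
marks a SNP whose urban-rural frequency shift is consistent across
localities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .popstruct import genotype_pca, mantel_test

__all__ = [
    "decompose_effects",
    "pc_level_decomposition",
    "shift_summary",
    "genes_under_selection",
    "sharing_null",
    "shared_sets_vs_distance",
    "overrepresentation",
]


# ---------------------------------------------------------------------------
# habitat x locality ANOVA
# ---------------------------------------------------------------------------

def _anova_decompose(y, habitat, locality):
    """Type-II two-way ANOVA of a response on habitat, locality, interaction."""
    df = pd.DataFrame({"y": y, "habitat": habitat, "locality": locality})
    n_cells = df.groupby(["habitat", "locality"]).ngroups
    if n_cells < df["habitat"].nunique() * df["locality"].nunique():
        raise ValueError("empty habitat x locality cell")
    model = ols("y ~ C(habitat) + C(locality) + C(habitat):C(locality)", df).fit()
    tab = anova_lm(model, typ=2)
    ss_res = tab.loc["Residual", "sum_sq"]
    out = {}
    for term, key in (
        ("C(habitat)", "habitat"),
        ("C(locality)", "locality"),
        ("C(habitat):C(locality)", "interaction"),
    ):
        ss = tab.loc[term, "sum_sq"]
        out[f"eta2_{key}"] = float(ss / (ss + ss_res)) if (ss + ss_res) > 0 else 0.0
        out[f"p_{key}"] = float(tab.loc[term, "PR(>F)"])
    out["consistent"] = out["eta2_habitat"] > out["eta2_interaction"]
    return out


def decompose_effects(panel, samples, snp_subset=None):
    """Per-SNP habitat/locality/interaction effect decomposition.

    Every locality must be sampled in both habitats. SNPs with constant
    dosage, or with an empty habitat x locality cell, are skipped and
    counted in ``.attrs["n_skipped"]``.
    """
    dos = panel.dosages()
    idx = (
        np.arange(panel.n_sites)
        if snp_subset is None
        else np.asarray(snp_subset, dtype=np.intp)
    )
    habitat = samples.df["habitat"].to_numpy()
    locality = samples.df["locality"].to_numpy()
    rows, skipped = [], 0
    for j in idx:
        y = dos[j].astype(float)
        if y.std() == 0:
            skipped += 1
            continue
        try:
            res = _anova_decompose(y, habitat, locality)
        except ValueError:
            skipped += 1
            continue
        rows.append(dict(snp=int(j), chrom=panel.chrom[j], pos=int(panel.pos[j]), **res))
    out = pd.DataFrame(
        rows,
        columns=["snp", "chrom", "pos", "eta2_habitat", "p_habitat",
                 "eta2_locality", "p_locality", "eta2_interaction",
                 "p_interaction", "consistent"],
    )
    out.attrs["n_skipped"] = skipped
    return out


def pc_level_decomposition(panel, samples, snp_subset, n_axes=3):
    """The same ANOVA applied to the first PC axes of the candidate SNPs."""
    scores, pve = genotype_pca(panel, snp_subset=snp_subset, n_components=n_axes)
    if scores.shape[1] < n_axes:
        raise ValueError(
            f"requested {n_axes} axes but candidate matrix has rank {scores.shape[1]}"
        )
    habitat = samples.df["habitat"].to_numpy()
    locality = samples.df["locality"].to_numpy()
    rows = []
    for a in range(n_axes):
        res = _anova_decompose(scores[:, a], habitat, locality)
        rows.append(dict(axis=a + 1, pve=float(pve[a]), **res))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# allele-frequency shifts and minor-allele concordance
# ---------------------------------------------------------------------------

def shift_summary(panel, samples, snp_subset=None):
    """Urban-rural frequency shifts and minor-allele concordance per SNP.

    For every locality pair: |dAF| = |p_urban - p_rural|. The global minor
    allele is defined across all urban populations pooled (ties at 0.5
    resolved toward ALT, deterministically); n_concordant counts urban
    populations whose local minor allele matches it, and n_direction counts
    localities in which the same allele strictly increased urban-ward
    (the better of the two alleles).
    """
    idx = (
        np.arange(panel.n_sites)
        if snp_subset is None
        else np.asarray(snp_subset, dtype=np.intp)
    )
    sub = panel.take_sites(idx)
    pairs = samples.pairs()
    if not pairs:
        raise ValueError("no locality has both habitats sampled")
    p_urb, p_rur = {}, {}
    for loc in pairs:
        p_urb[loc] = sub.alt_freq(sub.sample_index(samples.members(loc, "urban")))
        p_rur[loc] = sub.alt_freq(sub.sample_index(samples.members(loc, "rural")))
    U = np.vstack([p_urb[loc] for loc in pairs])   # n_pairs x S
    R = np.vstack([p_rur[loc] for loc in pairs])
    dAF = np.abs(U - R)
    pooled = U.mean(axis=0)
    # minor allele: ALT when pooled ALT freq <= 0.5 (tie -> ALT)
    global_minor_is_alt = pooled <= 0.5
    local_minor_is_alt = U <= 0.5
    n_concordant = (local_minor_is_alt == global_minor_is_alt[None, :]).sum(axis=0)
    alt_up = (U > R).sum(axis=0)
    ref_up = (U < R).sum(axis=0)
    n_direction = np.maximum(alt_up, ref_up)
    per_snp = pd.DataFrame(
        {
            "snp": idx,
            "chrom": sub.chrom,
            "pos": sub.pos,
            "mean_abs_daf": dAF.mean(axis=0),
            "n_concordant": n_concordant,
            "n_direction": n_direction,
        }
    )
    per_pair = pd.DataFrame(dAF.T, columns=[f"daf_{loc}" for loc in pairs])
    return pd.concat([per_snp, per_pair], axis=1)


# ---------------------------------------------------------------------------
# genes under selection and the sharing null
# ---------------------------------------------------------------------------

def genes_under_selection(regions_by_population, genes):
    """Gene sets flagged per population by outlier-region overlap.

    A gene is flagged for a population iff its [start, end) interval
    intersects any of that population's outlier regions by at least 1 bp
    (half-open semantics: abutting intervals do not overlap).
    """
    out = {}
    for pop, regions in regions_by_population.items():
        trees = {}
        for _, r in pd.DataFrame(regions).iterrows():
            if r["end"] > r["start"]:
                trees.setdefault(r["chrom"], IntervalTree()).addi(
                    int(r["start"]), int(r["end"])
                )
        hits = set()
        for _, g in genes.iterrows():
            tree = trees.get(g["chrom"])
            if tree is not None and tree.overlap(int(g["start"]), int(g["end"])):
                hits.add(g["gene_id"])
        out[pop] = hits
    return out


def sharing_null(gene_sets, universe, reps=100_000, seed=0, batch=2_000,
                 draw_counts=None):
    """Resampling null for the number of genes shared across populations.

    For each replicate and population, n_p genes are drawn *with
    replacement* from the universe of SNP-linked genes and reduced to a
    unique set; the count of genes present in >= k of the P sets is
    recorded for k = 2..P. By default n_p is the size of that population's
    observed gene set (the study convention); ``draw_counts`` (mapping
    population -> count) overrides it, e.g. for calibration studies where
    the generating draw count is known. Returns a table per k with the null
    mean, percentile 95% CI, the observed count from the real sets, and the
    Monte-Carlo p = (1 + #{null >= observed}) / (reps + 1).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    universe = list(universe)
    G = len(universe)
    gene_pos = {g: i for i, g in enumerate(universe)}
    pops = sorted(gene_sets)
    P = len(pops)
    sizes = []
    obs_matrix = np.zeros((P, G), dtype=bool)
    for i, pop in enumerate(pops):
        s = set(gene_sets[pop])
        if not s <= set(universe):
            raise ValueError(f"gene set for {pop!r} not contained in the universe")
        sizes.append(len(s) if draw_counts is None else int(draw_counts[pop]))
        for g in s:
            obs_matrix[i, gene_pos[g]] = True
    counts_obs = obs_matrix.sum(axis=0)
    ks = np.arange(2, P + 1)
    observed = np.array([(counts_obs >= k).sum() for k in ks])

    rng = np.random.default_rng(seed)
    null = np.empty((reps, len(ks)), dtype=np.int32)
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        counts = np.zeros((b, G), dtype=np.int16)
        for n_p in sizes:
            if n_p == 0:
                continue
            draws = rng.integers(0, G, size=(b, n_p))
            offset = draws + (np.arange(b)[:, None] * G)
            binc = np.bincount(offset.ravel(), minlength=b * G).reshape(b, G)
            counts += (binc > 0).astype(np.int16)
        for kj, k in enumerate(ks):
            null[done : done + b, kj] = (counts >= k).sum(axis=1)
        done += b

    rows = []
    for kj, k in enumerate(ks):
        col = null[:, kj]
        rows.append(
            dict(
                k=int(k),
                null_mean=float(col.mean()),
                null_ci_low=float(np.percentile(col, 2.5)),
                null_ci_high=float(np.percentile(col, 97.5)),
                observed=int(observed[kj]),
                p=float((1 + (col >= observed[kj]).sum()) / (reps + 1)),
            )
        )
    return pd.DataFrame(rows)


def shared_sets_vs_distance(shared_counts, genetic_dist, geo_dist,
                            n_perm=999, seed=0):
    """Mantel tests of pairwise sharing against genetic and geographic distance.

    ``shared_counts`` is a square similarity matrix (shared outlier genes or
    windows between urban populations); it is negated into a distance before
    the Mantel tests. Returns {"genetic": MantelResult, "geographic": ...}.
    """
    S = np.asarray(shared_counts, dtype=float)
    D = S.max() - S
    np.fill_diagonal(D, 0.0)
    return {
        "genetic": mantel_test(D, genetic_dist, n_perm=n_perm, seed=seed),
        "geographic": mantel_test(D, geo_dist, n_perm=n_perm, seed=seed),
    }


# ---------------------------------------------------------------------------
# overrepresentation
# ---------------------------------------------------------------------------

def overrepresentation(geneset, annotation, universe, fdr=0.05):
    """Hypergeometric term-overrepresentation for a gene set.

    ``annotation`` maps gene -> iterable of terms; only universe genes
    count. Per term: upper-tail P(X >= overlap) for drawing |geneset| genes
    from the universe; Benjamini-Hochberg FDR; significant at FDR < 0.05.
    """
    geneset = set(geneset)
    universe = set(universe)
    if not geneset:
        raise ValueError("empty gene set")
    if not geneset <= universe:
        raise ValueError("gene set must be contained in the universe")
    term_members = {}
    for gene, terms in annotation.items():
        if gene not in universe:
            continue
        for t in terms:
            term_members.setdefault(t, set()).add(gene)
    rows = []
    N, n = len(universe), len(geneset)
    for term, members in sorted(term_members.items()):
        K = len(members)
        k = len(members & geneset)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append(dict(term=term, term_size=K, overlap=k, p=p))
    df = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["q"] < fdr
    else:
        df["q"] = []
        df["significant"] = []
    return df
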