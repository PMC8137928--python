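"""Independent brute-force oracles used by the test suite.

Each function re-derives a statistic from first principles by a route
deliberately different from the package implementation (scalar loops,
exhaustive enumeration, nested-model residual comparisons), so agreement is
evidence of correctness rather than shared code.
"""

import math

import numpy as np


def wc_theta_scalar(genosA, genosB):
    """Weir & Cockerham (1984) theta-hat for one SNP, scalar arithmetic.

    genosA/genosB: lists of diploid genotypes coded 0/1/2.
    Returns NaN when a + b + c == 0.
    """
    nA, nB = len(genosA), len(genosB)
    r = 2
    pA = sum(genosA) / (2 * nA)
    pB = sum(genosB) / (2 * nB)
    hA = sum(1 for g in genosA if g == 1) / nA
    hB = sum(1 for g in genosB if g == 1) / nB
    n_bar = (nA + nB) / r
    n_c = (r * n_bar - (nA * nA + nB * nB) / (r * n_bar)) / (r - 1)
    p_bar = (nA * pA + nB * pB) / (r * n_bar)
    s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (nA * hA + nB * hB) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - (r - 1) / r * s2
        - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    tot = a + b + c
    return a / tot if tot != 0 else float("nan")


def ehh_enumeration(haps, core, core_allele, target):
    """EHH at `target` by exhaustive pair enumeration over carrier haplotypes."""
    lo, hi = (core, target) if target >= core else (target, core)
    carriers = [i for i in range(haps.shape[0]) if haps[i, core] == core_allele]
    pairs = ident = 0
    for a in range(len(carriers)):
        for b in range(a + 1, len(carriers)):
            pairs += 1
            if np.array_equal(haps[carriers[a], lo:hi + 1], haps[carriers[b], lo:hi + 1]):
                ident += 1
    return ident / pairs


def ehhs_enumeration(haps, core, target):
    """EHHS at `target`: pairs identical over [core..target] / pairs identical at core."""
    lo, hi = (core, target) if target >= core else (target, core)
    n = haps.shape[0]
    at_core = over_interval = 0
    for a in range(n):
        for b in range(a + 1, n):
            if haps[a, core] == haps[b, core]:
                at_core += 1
                if np.array_equal(haps[a, lo:hi + 1], haps[b, lo:hi + 1]):
                    over_interval += 1
    return over_interval / at_core if at_core else float("nan")


def ies_trapezoid(positions, values, core_pos, cutoff):
    """Explicit-loop trapezoidal integral of a one-sided decay curve."""
    total = 0.0
    for k in range(1, len(values)):
        if values[k] < cutoff:
            break
        d0 = abs(positions[k - 1] - core_pos)
        d1 = abs(positions[k] - core_pos)
        total += (d1 - d0) * (values[k] + values[k - 1]) / 2.0
    return total


def nsl_pair_outward(h1, h2, core):
    """Shared-interval length at `core` by outward scanning, one pair."""
    if h1[core] != h2[core]:
        return 0
    S = len(h1)
    left = core
    while left - 1 >= 0 and h1[left - 1] == h2[left - 1]:
        left -= 1
    right = core
    while right + 1 < S and h1[right + 1] == h2[right + 1]:
        right += 1
    return right - left + 1


def eta2_type2(y, habitat, locality):
    """Partial eta^2 by nested-model residual comparison (type-II SS)."""

    def design(terms):
        cols = [np.ones(len(y))]
        hab_levels = sorted(set(habitat))[1:]
        loc_levels = sorted(set(locality))[1:]
        if "h" in terms:
            cols += [(np.array(habitat) == l).astype(float) for l in hab_levels]
        if "l" in terms:
            cols += [(np.array(locality) == l).astype(float) for l in loc_levels]
        if "i" in terms:
            for a in hab_levels:
                for b in loc_levels:
                    cols.append(
                        ((np.array(habitat) == a) & (np.array(locality) == b)).astype(float)
                    )
        return np.column_stack(cols)

    def rss(terms):
        X = design(terms)
        beta, *_ = np.linalg.lstsq(X, np.asarray(y, dtype=float), rcond=None)
        r = np.asarray(y, dtype=float) - X @ beta
        return float(r @ r)

    rss_full = rss("hli")
    ss = {
        "habitat": rss("l") - rss("hl"),
        "locality": rss("h") - rss("hl"),
        "interaction": rss("hl") - rss_full,
    }
    return {k: v / (v + rss_full) if (v + rss_full) > 0 else 0.0 for k, v in ss.items()}


def hypergeom_tail(k, N, K, n):
    """P(X >= k) by exhaustive summation of the hypergeometric pmf."""
    total = 0.0
    for i in range(k, min(K, n) + 1):
        total += math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
    return total


def window_members(positions, start, end):
    """Brute-force membership of 1-based positions in [start, end)."""
    return [i for i, p in enumerate(positions) if start <= p - 1 < end]


def vif_prune_exhaustive(dosages, threshold):
    """Remove max-VIF SNPs one at a time, VIFs by full matrix inversion."""
    active = [i for i in range(dosages.shape[0]) if np.std(dosages[i]) > 0]
    while len(active) > 1:
        R = np.corrcoef(dosages[active])
        R[np.diag_indices_from(R)] += 1e-8
        vifs = np.diag(np.linalg.inv(R))
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        active.pop(worst)
    keep_poly = set(active)
    mono = [i for i in range(dosages.shape[0]) if np.std(dosages[i]) == 0]
    return sorted(keep_poly | set(mono))
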