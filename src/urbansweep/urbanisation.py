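"""Urbanisation score (PC_urb) from land-cover proportions, and scorer ICC.

Each site is covered by 100 m grid cells scored for the proportion of
buildings, vegetation and paved surface. Per-site means of the three cover
variables enter a correlation-matrix PCA; the first principal component,
oriented so that more built surface means a higher score, is the
urbanisation score PC_urb (negative at less urbanised sites, positive at
more urbanised ones).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["score_urbanisation", "average_multisite", "icc_repeatability"]

_COVER_VARS = ["p_buildings", "p_vegetation", "p_paved"]
# preference order for fixing the PC1 sign: built surface loads positive,
# vegetation negative
_ORIENT = [("p_buildings", +1), ("p_paved", +1), ("p_vegetation", -1)]


def score_urbanisation(landcover):
    """Per-site urbanisation score from a cell-level land-cover table.

    Returns a DataFrame (site_id, pc_urb) with ``loadings`` (per retained
    cover variable) and ``pve`` (PC1 proportion of variance explained)
    attached in ``.attrs``. Cover variables constant across sites carry no
    information and are dropped; if all three are constant the PCA is
    undefined and a ValueError is raised.
    """
    lc = pd.DataFrame(landcover)
    site_means = lc.groupby("site_id", sort=True)[_COVER_VARS].mean()
    if len(site_means) < 3:
        raise ValueError("need at least 3 sites for a PCA-based score")
    sd = site_means.std(ddof=1)
    keep = [v for v in _COVER_VARS if sd[v] > 0]
    if not keep:
        raise ValueError("all cover variables have zero variance across sites")
    X = (site_means[keep] - site_means[keep].mean()) / site_means[keep].std(ddof=1)
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pc1 = evecs[:, 0]
    for var, sign in _ORIENT:
        if var in keep:
            load = pc1[keep.index(var)]
            if load != 0:
                if np.sign(load) != sign:
                    pc1 = -pc1
                break
    scores = X.to_numpy() @ pc1
    out = pd.DataFrame({"site_id": site_means.index, "pc_urb": scores})
    out.attrs["loadings"] = dict(zip(keep, pc1))
    out.attrs["pve"] = float(evals[0] / evals.sum())
    return out


def average_multisite(scores, site_groups):
    """Average per-site scores within groups (multi-site captures per locality).

    ``scores``: mapping or Series site_id -> value; ``site_groups``: mapping
    group -> list of site_ids. Empty groups are an error.
    """
    if isinstance(scores, pd.DataFrame):
        s = scores.set_index("site_id")["pc_urb"]
    elif isinstance(scores, pd.Series):
        s = scores
    else:
        s = pd.Series(scores)
    out = {}
    for group, members in site_groups.items():
        if not members:
            raise ValueError(f"empty site group {group!r}")
        out[group] = float(s.loc[list(members)].mean())
    return pd.Series(out)


def icc_repeatability(measurements):
    """Two-way mixed-effects, absolute-agreement, single-measure ICC.

    ``measurements`` is a sites x replicates matrix (same scorer replicates
    in columns). Computed from the two-way ANOVA mean squares:

        ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

    with MS_R rows (sites), MS_C columns (replicates), MS_E residual.
    Undefined (error) when any site has fewer than two replicates or when
    there is no between-site variance.
    """
    X = np.asarray(measurements, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a sites x replicates matrix with >= 2 replicates")
    if np.isnan(X).any():
        raise ValueError("missing replicate measurements are not supported")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if ms_r <= 0 or denom == 0:
        raise ValueError("no between-site variance; ICC undefined")
    return float((ms_r - ms_e) / denom)
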