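"""Forward-time Wright-Fisher simulator of paired urban-rural demes.

The generator emulates the structure of a paired-deme urban-adaptation
study: ``n_localities`` localities, each with a long-established rural deme
and an urban deme founded more recently through a bottleneck from its rural
neighbour. Discrete non-overlapping generations; each offspring draws two
parents multinomially with weights proportional to fitness; each gamete is
formed by Poisson-distributed crossovers and per-site mutation. Migration
swaps individuals symmetrically: rural demes exchange migrants with each
other at rate ``m_rr`` (each individual is, with that probability, swapped
with one from a uniformly chosen other rural deme), and each urban deme
exchanges with its paired rural deme at rate ``m_ur``.

Selection operates in urban demes only: planted hard sweeps multiply
fitness by ``(1 + s * dosage)`` at the sweep locus, and an optional
polygenic trait is under Gaussian stabilising selection with the optimum
displaced by ``optimum_shift`` in urban demes.

Standing variation is initialised from a 1/f-shaped site frequency
spectrum rather than accumulated through a mutation-only burn-in, so that
desk-scale runs start segregating; the burn-in generations then build up
linkage disequilibrium consistent with the recombination rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import HaplotypePanel, SampleFrame

__all__ = [
    "SweepSpec",
    "PolygenicLocus",
    "SimConfig",
    "simulate_panel",
    "sample_panel_from_frequencies",
    "generate_sites",
    "generate_landcover",
    "truth_recall",
]


@dataclass
class SweepSpec:
    """A planted hard sweep: positively selected in one urban deme."""

    locality: str
    chrom: str
    pos: int
    s: float
    init_freq: float = 0.005  # ~single copy among 2*founder_size haplotypes
    habitat: str = "urban"


@dataclass
class PolygenicLocus:
    chrom: str
    pos: int
    effect_size: float


@dataclass
class SimConfig:
    """Parameters of the paired-deme simulation (desk-scale defaults)."""

    n_localities: int = 9
    N_anc: int = 400
    N_rural: int = 200
    N_urban: int = 200
    founder_size: int = 100
    t_burnin: int = 40
    t_split: int = 60
    t_urban: int = 45
    m_rr: float = 0.01
    m_ur: float = 0.005
    mu: float = 1e-7
    rho: float = 8e-7
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000, "chrZ": 8_000_000}
    )
    z_chroms: tuple = ("chrZ",)
    n_sites_target: int = 3000
    sweeps: list = field(default_factory=list)
    polygenic: list = field(default_factory=list)
    optimum_shift: float = 0.0
    omega: float = 1.0
    sample_range: tuple = (10, 16)
    condition_on_sweep: bool = False
    retry_cap: int = 20
    min_init_freq: float = 0.05
    max_init_freq: float = 0.95
    seed: int = 0

    def __post_init__(self):
        for name in ("m_rr", "m_ur", "mu", "rho"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name}={v} outside [0, 1)")
        for name in ("N_anc", "N_rural", "N_urban", "founder_size"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        for sw in self.sweeps:
            if not (1 <= sw.pos <= self.chrom_lengths[sw.chrom]):
                raise ValueError(f"sweep position {sw.pos} outside {sw.chrom}")
        for pl in self.polygenic:
            if not (1 <= pl.pos <= self.chrom_lengths[pl.chrom]):
                raise ValueError(f"polygenic position {pl.pos} outside {pl.chrom}")

    def chrom_class(self):
        return {
            c: ("Z" if c in self.z_chroms else "autosome") for c in self.chrom_lengths
        }


class SweepLostError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# site map
# ---------------------------------------------------------------------------

def _build_site_map(cfg, rng):
    """Positions per chromosome (1-based, strictly increasing), planted loci included."""
    total = sum(cfg.chrom_lengths.values())
    chroms, positions = [], []
    planted = {}
    for c, L in cfg.chrom_lengths.items():
        n = max(2, round(cfg.n_sites_target * L / total))
        pos = np.sort(rng.choice(np.arange(1, L + 1), size=min(n, L), replace=False))
        must = sorted(
            {sw.pos for sw in cfg.sweeps if sw.chrom == c}
            | {pl.pos for pl in cfg.polygenic if pl.chrom == c}
        )
        if must:
            pos = np.unique(np.concatenate([pos, np.array(must, dtype=np.int64)]))
        chroms.extend([c] * len(pos))
        positions.append(pos)
    pos_all = np.concatenate(positions) if positions else np.empty(0, dtype=np.int64)
    chrom_all = np.array(chroms, dtype=object)
    index = {}
    for i, (c, p) in enumerate(zip(chrom_all, pos_all)):
        index[(c, int(p))] = i
    return chrom_all, pos_all, index


def _init_frequencies(cfg, n_sites, rng):
    """Standing-variation frequencies drawn from a 1/f-shaped spectrum."""
    lo, hi = cfg.min_init_freq, cfg.max_init_freq
    u = rng.random(n_sites)
    return lo * (hi / lo) ** u


# ---------------------------------------------------------------------------
# reproduction machinery
# ---------------------------------------------------------------------------

def _make_gametes(haps, parent_idx, chrom_slices, chrom_len_list, rho, rng):
    """One gamete per entry of parent_idx. haps: (2N, S)."""
    n = len(parent_idx)
    S = haps.shape[1]
    out = np.empty((n, S), dtype=np.int8)
    start_hap = rng.integers(0, 2, size=(n, len(chrom_slices)))
    # crossover counts per gamete per chromosome
    xo_counts = rng.poisson(
        np.array(chrom_len_list, dtype=float) * rho, size=(n, len(chrom_slices))
    )
    for g in range(n):
        p = parent_idx[g]
        h0 = haps[2 * p]
        h1 = haps[2 * p + 1]
        for ci, (sl, pos) in enumerate(chrom_slices):
            k = xo_counts[g, ci]
            first = start_hap[g, ci]
            if k == 0:
                out[g, sl] = h1[sl] if first else h0[sl]
                continue
            bps = np.sort(rng.integers(1, chrom_len_list[ci] + 1, size=k))
            # parity of breakpoints before each site decides source haplotype
            parity = (np.searchsorted(bps, pos, side="left") + first) % 2
            seg0 = h0[sl]
            seg1 = h1[sl]
            out[g, sl] = np.where(parity == 0, seg0, seg1)
    return out


class _Deme:
    def __init__(self, haps, habitat, locality):
        self.haps = haps  # (2N, S) int8
        self.habitat = habitat
        self.locality = locality

    @property
    def n(self):
        return self.haps.shape[0] // 2


def _fitness(deme, sel_sites, sel_s, poly_sites, poly_eff, opt, omega):
    """Per-individual fitness in a deme."""
    n = deme.n
    w = np.ones(n)
    d = deme.haps[0::2] + deme.haps[1::2]  # (n, S) dosage view by haplotype row pairing
    for j, s in zip(sel_sites, sel_s):
        w *= 1.0 + s * d[:, j]
    if poly_sites:
        z = d[:, poly_sites] @ np.asarray(poly_eff, dtype=float)
        w *= np.exp(-((z - opt) ** 2) / (2.0 * omega**2))
    return w


def _reproduce(deme, n_off, chrom_slices, chrom_len_list, cfg, rng,
               sel_sites=(), sel_s=(), poly_sites=(), poly_eff=(), opt=0.0):
    w = _fitness(deme, sel_sites, sel_s, poly_sites, poly_eff, opt, cfg.omega)
    tot = w.sum()
    if tot <= 0:
        w = np.ones(len(w))
        tot = w.sum()
    p = w / tot
    mothers = rng.choice(deme.n, size=n_off, p=p)
    fathers = rng.choice(deme.n, size=n_off, p=p)
    g_m = _make_gametes(deme.haps, mothers, chrom_slices, chrom_len_list, cfg.rho, rng)
    g_f = _make_gametes(deme.haps, fathers, chrom_slices, chrom_len_list, cfg.rho, rng)
    haps = np.empty((2 * n_off, g_m.shape[1]), dtype=np.int8)
    haps[0::2] = g_m
    haps[1::2] = g_f
    # mutation: 0 <-> 1 flips, Bernoulli(mu) per site per haplotype
    if cfg.mu > 0:
        n_mut = rng.poisson(cfg.mu * haps.size)
        if n_mut:
            rr = rng.integers(0, haps.shape[0], size=n_mut)
            cc = rng.integers(0, haps.shape[1], size=n_mut)
            haps[rr, cc] ^= 1
    return _Deme(haps, deme.habitat, deme.locality)


def _swap_individuals(a, b, n_swap, rng):
    if n_swap <= 0:
        return
    ia = rng.choice(a.n, size=n_swap, replace=False)
    ib = rng.choice(b.n, size=n_swap, replace=False)
    rows_a = np.concatenate([2 * ia, 2 * ia + 1])
    rows_b = np.concatenate([2 * ib, 2 * ib + 1])
    tmp = a.haps[rows_a].copy()
    a.haps[rows_a] = b.haps[rows_b]
    b.haps[rows_b] = tmp


def _migrate(rural, urban, cfg, rng):
    # rural-rural: each individual with prob m_rr is swapped with one from a
    # uniformly chosen other rural deme
    k = len(rural)
    if k > 1 and cfg.m_rr > 0:
        for i in range(k):
            n_mig = rng.binomial(rural[i].n, cfg.m_rr)
            for _ in range(n_mig):
                j = rng.choice([x for x in range(k) if x != i])
                _swap_individuals(rural[i], rural[j], 1, rng)
    # urban-rural within pair
    if cfg.m_ur > 0:
        for i, u in urban.items():
            n_mig = rng.binomial(min(u.n, rural[i].n), cfg.m_ur)
            _swap_individuals(u, rural[i], n_mig, rng)


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------

def simulate_panel(config, seed=None):
    """Run the paired-deme forward simulation.

    Returns (panel, samples, truth): a phased :class:`HaplotypePanel` of
    10-16 sampled diploids per deme, the matching :class:`SampleFrame`, and
    a truth table with one row per planted locus per deme holding the
    realised final allele frequency (enables parameter-recovery checks).

    Deterministic under a fixed seed. With ``condition_on_sweep`` the run is
    resampled (up to ``retry_cap`` times) until no sweep allele is lost;
    otherwise losses are simply recorded in the truth table.
    """
    cfg = config
    base_seed = cfg.seed if seed is None else seed
    for attempt in range(max(1, cfg.retry_cap if cfg.condition_on_sweep else 1)):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, attempt]))
        result = _simulate_once(cfg, rng)
        panel, samples, truth = result
        if not cfg.condition_on_sweep:
            return result
        lost = truth[(truth["type"] == "sweep") & truth["lost"]]
        if lost.empty:
            return result
    raise SweepLostError(
        f"sweep allele lost in all {cfg.retry_cap} conditioned attempts"
    )


def _simulate_once(cfg, rng):
    chrom_all, pos_all, site_index = _build_site_map(cfg, rng)
    S = len(pos_all)
    chrom_names = list(cfg.chrom_lengths)
    chrom_slices = []
    chrom_len_list = []
    for c in chrom_names:
        mask = chrom_all == c
        idx = np.flatnonzero(mask)
        sl = slice(idx[0], idx[-1] + 1) if len(idx) else slice(0, 0)
        chrom_slices.append((sl, pos_all[sl]))
        chrom_len_list.append(cfg.chrom_lengths[c])

    freqs = _init_frequencies(cfg, S, rng)
    # sweep alleles are new mutations planted at urban founding: absent from
    # the ancestral standing variation
    for sw in cfg.sweeps:
        freqs[site_index[(sw.chrom, sw.pos)]] = 0.0
    localities = [f"L{i + 1}" for i in range(cfg.n_localities)]

    # ancestral deme + burn-in
    anc = _Deme(
        (rng.random((2 * cfg.N_anc, S)) < freqs).astype(np.int8), "rural", "anc"
    )
    for _ in range(cfg.t_burnin):
        anc = _reproduce(anc, cfg.N_anc, chrom_slices, chrom_len_list, cfg, rng)

    # split into rural demes
    rural = []
    for loc in localities:
        d = _reproduce(anc, cfg.N_rural, chrom_slices, chrom_len_list, cfg, rng)
        d.locality = loc
        rural.append(d)
    for _ in range(cfg.t_split):
        rural = [
            _reproduce(d, cfg.N_rural, chrom_slices, chrom_len_list, cfg, rng)
            for d in rural
        ]
        _migrate(rural, {}, cfg, rng)

    # urban founding
    sweeps_by_loc = {}
    for sw in cfg.sweeps:
        sweeps_by_loc.setdefault(sw.locality, []).append(sw)
    poly_sites = [site_index[(pl.chrom, pl.pos)] for pl in cfg.polygenic]
    poly_eff = [pl.effect_size for pl in cfg.polygenic]

    urban = {}
    for i, loc in enumerate(localities):
        founders = rng.choice(cfg.N_rural, size=min(cfg.founder_size, cfg.N_rural),
                              replace=False)
        rows = np.concatenate([2 * founders, 2 * founders + 1])
        u = _Deme(rural[i].haps[rows].copy(), "urban", loc)
        # plant sweep alleles at init_freq among founder haplotypes; all
        # carriers share one donor background on the sweep chromosome
        # (single mutational origin -> hard sweep, not a soft one)
        for sw in sweeps_by_loc.get(loc, []):
            j = site_index[(sw.chrom, sw.pos)]
            ci = chrom_names.index(sw.chrom)
            sl = chrom_slices[ci][0]
            n_hap = u.haps.shape[0]
            n_carriers = max(1, round(sw.init_freq * n_hap))
            carriers = rng.choice(n_hap, size=n_carriers, replace=False)
            u.haps[carriers[1:], sl] = u.haps[carriers[0], sl]
            u.haps[:, j] = 0
            u.haps[carriers, j] = 1
        urban[i] = u

    for _ in range(cfg.t_urban):
        new_rural = [
            _reproduce(d, cfg.N_rural, chrom_slices, chrom_len_list, cfg, rng)
            for d in rural
        ]
        new_urban = {}
        for i, u in urban.items():
            loc = localities[i]
            sws = sweeps_by_loc.get(loc, [])
            sel_sites = [site_index[(sw.chrom, sw.pos)] for sw in sws]
            sel_s = [sw.s for sw in sws]
            new_urban[i] = _reproduce(
                u, cfg.N_urban, chrom_slices, chrom_len_list, cfg, rng,
                sel_sites=sel_sites, sel_s=sel_s,
                poly_sites=poly_sites, poly_eff=poly_eff,
                opt=cfg.optimum_shift,
            )
        rural = new_rural
        urban = new_urban
        _migrate(rural, urban, cfg, rng)

    # final sampling
    lo, hi = cfg.sample_range
    sample_ids, hap_cols, meta = [], [], []
    all_demes = []
    for i, loc in enumerate(localities):
        all_demes.append((loc, "urban", urban[i]))
        all_demes.append((loc, "rural", rural[i]))
    panels_rows = []
    for loc, hab, deme in all_demes:
        n_take = int(rng.integers(lo, hi + 1))
        n_take = min(n_take, deme.n)
        take = np.sort(rng.choice(deme.n, size=n_take, replace=False))
        for k, t in enumerate(take):
            sid = f"{loc}{'U' if hab == 'urban' else 'R'}_{k + 1:02d}"
            sample_ids.append(sid)
            meta.append(dict(individual=sid, locality=loc, habitat=hab,
                             sex=("F" if rng.random() < 0.5 else "M")))
            panels_rows.append(deme.haps[2 * t])
            panels_rows.append(deme.haps[2 * t + 1])
    haps = np.array(panels_rows, dtype=np.int8).T  # (S, 2*n_samples)

    panel = HaplotypePanel(
        sample_ids=sample_ids,
        chrom=chrom_all,
        pos=pos_all,
        ref_allele=np.array(["A"] * S, dtype=object),
        alt_allele=np.array(["T"] * S, dtype=object),
        haplotypes=haps,
        chrom_class=cfg.chrom_class(),
    )
    samples = SampleFrame(pd.DataFrame(meta))

    # truth table: realised frequency per planted locus per deme
    rows = []
    for loc, hab, deme in all_demes:
        for sw in cfg.sweeps:
            j = site_index[(sw.chrom, sw.pos)]
            f = float(deme.haps[:, j].mean())
            rows.append(dict(locality=loc, habitat=hab, chrom=sw.chrom, pos=sw.pos,
                             type="sweep", coef=sw.s, final_freq=f,
                             lost=(f == 0.0 and loc == sw.locality and hab == "urban")))
        for pl in cfg.polygenic:
            j = site_index[(pl.chrom, pl.pos)]
            f = float(deme.haps[:, j].mean())
            rows.append(dict(locality=loc, habitat=hab, chrom=pl.chrom, pos=pl.pos,
                             type="polygenic", coef=pl.effect_size, final_freq=f,
                             lost=(f == 0.0)))
    truth = pd.DataFrame(
        rows,
        columns=["locality", "habitat", "chrom", "pos", "type", "coef",
                 "final_freq", "lost"],
    )
    return panel, samples, truth


# ---------------------------------------------------------------------------
# fast linkage-free panel generator (association calibration / power)
# ---------------------------------------------------------------------------

def sample_panel_from_frequencies(freqs, pop_sizes, positions=None, chrom="chr1",
                                  chrom_length=None, seed=0, chrom_class=None):
    """Draw a linkage-free phased panel at specified per-population frequencies.

    ``freqs`` is (n_pops, n_sites); ``pop_sizes`` a list of (locality,
    habitat, n_diploids). Each haplotype allele is an independent Bernoulli
    draw at its population's frequency — no linkage, no drift — so planted
    frequency differences are exact in expectation. Suited to
    genotype-environment association calibration; use :func:`simulate_panel`
    wherever haplotype structure matters.
    """
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    n_pops, S = freqs.shape
    if len(pop_sizes) != n_pops:
        raise ValueError("pop_sizes length must match freqs rows")
    if positions is None:
        L = chrom_length or (S * 1000 + 1000)
        positions = np.sort(
            rng.choice(np.arange(1, L + 1), size=S, replace=False)
        )
    sample_ids, meta, cols = [], [], []
    for p, (loc, hab, n) in enumerate(pop_sizes):
        draws = (rng.random((S, 2 * n)) < freqs[p][:, None]).astype(np.int8)
        cols.append(draws)
        for k in range(n):
            sid = f"{loc}{'U' if hab == 'urban' else 'R'}_{k + 1:02d}"
            sample_ids.append(sid)
            meta.append(dict(individual=sid, locality=loc, habitat=hab, sex="unknown"))
    haps = np.concatenate(cols, axis=1)
    return (
        HaplotypePanel(
            sample_ids=sample_ids,
            chrom=np.array([chrom] * S, dtype=object),
            pos=np.asarray(positions, dtype=np.int64),
            ref_allele=np.array(["A"] * S, dtype=object),
            alt_allele=np.array(["T"] * S, dtype=object),
            haplotypes=haps,
            chrom_class=dict(chrom_class or {chrom: "autosome"}),
        ),
        SampleFrame(pd.DataFrame(meta)),
    )


# ---------------------------------------------------------------------------
# sites, land cover, truth recall
# ---------------------------------------------------------------------------

def generate_sites(n_localities=9, seed=0, urban_intensity_range=(0.55, 0.95),
                   rural_intensity_range=(0.02, 0.3)):
    """Synthetic site table: coordinates plus an urban-intensity per site.

    Localities are scattered over a roughly European extent; each urban site
    sits a few km from its rural partner. Returns a DataFrame usable as
    SiteInfo with an extra ``urban_intensity`` column feeding
    :func:`generate_landcover`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_localities):
        loc = f"L{i + 1}"
        lon = rng.uniform(-9, 25)
        lat = rng.uniform(37, 58)
        d_lon, d_lat = rng.normal(0, 0.05, 2)
        rows.append(dict(site_id=f"{loc}_urban", locality=loc, habitat="urban",
                         longitude=lon, latitude=lat,
                         urban_intensity=rng.uniform(*urban_intensity_range)))
        rows.append(dict(site_id=f"{loc}_rural", locality=loc, habitat="rural",
                         longitude=lon + d_lon + 0.15, latitude=lat + d_lat,
                         urban_intensity=rng.uniform(*rural_intensity_range)))
    return pd.DataFrame(rows)


def generate_landcover(sites, urban_intensity, seed=0, n_cells=100,
                       concentration=60.0):
    """Synthetic land-cover proportions for 100 m grid cells per site.

    Each site gets ``n_cells`` cells whose (buildings, vegetation, paved)
    proportions are Dirichlet draws around a target mixture whose
    built-surface mass increases monotonically with ``urban_intensity``:
    target = (0.6 u, 1 - u, 0.4 u). ``concentration=None`` gives the exact
    target in every cell (zero noise). Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    intensity = np.asarray(urban_intensity, dtype=float)
    site_ids = list(sites["site_id"])
    if len(intensity) != len(site_ids):
        raise ValueError("one urban_intensity value per site required")
    if ((intensity < 0) | (intensity > 1)).any():
        raise ValueError("urban_intensity outside [0, 1]")
    rows = []
    for sid, u in zip(site_ids, intensity):
        target = np.array([0.6 * u, 1.0 - u, 0.4 * u])
        if concentration is None:
            cells = np.tile(target, (n_cells, 1))
        else:
            alpha = np.maximum(target * concentration, 1e-9)
            cells = rng.dirichlet(alpha, size=n_cells)
            cells[:, target == 0] = 0.0
            cells /= cells.sum(axis=1, keepdims=True)
        for k in range(n_cells):
            rows.append(dict(site_id=sid, cell_id=f"cell{k + 1:03d}",
                             p_buildings=cells[k, 0], p_vegetation=cells[k, 1],
                             p_paved=cells[k, 2]))
    return pd.DataFrame(rows)


def truth_recall(truth, regions, slack=100_000):
    """Flag each planted locus as detected by the merged outlier regions.

    A locus is detected iff it lies inside a region or within ``slack`` bp
    of one; the returned table carries the distance to the nearest region
    (0 when contained, inf when the region set is empty).
    """
    regions = pd.DataFrame(regions) if not isinstance(regions, pd.DataFrame) else regions
    loci = truth[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    out = []
    for _, locus in loci.iterrows():
        p0 = locus["pos"] - 1  # interval coordinate of the SNP
        best = np.inf
        if len(regions):
            sub = regions[regions["chrom"] == locus["chrom"]]
            for _, r in sub.iterrows():
                if r["start"] <= p0 < r["end"]:
                    best = 0
                    break
                d = r["start"] - p0 if p0 < r["start"] else p0 - (r["end"] - 1)
                best = min(best, d)
        out.append(dict(chrom=locus["chrom"], pos=locus["pos"],
                        distance=best, detected=bool(best <= slack)))
    return pd.DataFrame(out, columns=["chrom", "pos", "distance", "detected"])
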