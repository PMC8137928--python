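"""End-to-end pipeline: simulate -> urbanisation score -> structure -> GEA ->
haplotype scans -> window outliers -> gene sharing, from one YAML config.

Every stage's defaults are the study conventions: 200 kb windows / 50 kb
steps, FDR < 1% for the latent-factor GEA, dB > 20 for the covariance
association, Rsb >= 4 and XP-nSL > 2 SNP thresholds, 95th-percentile dual
window criterion, 200 kb merge gap, 100,000 sharing-resampling replicates.
A single global seed is expanded per stage through a counter-based
SeedSequence scheme so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as uio
from . import sharing as ush
from . import windows as uwin
from .gea import (core_intersection, covariance_association,
                  env_to_individuals, latent_factor_gea)
from .panel import population_label
from .popstruct import expected_heterozygosity, ld_prune, wc_fst
from .simulate import (SimConfig, SweepSpec, PolygenicLocus, generate_landcover,
                       generate_sites, simulate_panel)
from .sweepscan import rsb_scan, xpnsl_scan
from .urbanisation import score_urbanisation

log = logging.getLogger("urbansweep")

STAGES = ("simulate", "urbscore", "structure", "gea", "scan", "windows", "share")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "urbansweep_out"
    sim: dict = field(default_factory=dict)
    urbscore: dict = field(default_factory=dict)
    structure: dict = field(default_factory=dict)
    gea: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    share: dict = field(default_factory=dict)

    _KNOWN = {
        "seed", "out_dir", "sim", "urbscore", "structure", "gea", "scan",
        "windows", "share",
    }
    _KNOWN_SUB = {
        "sim": {f.name for f in SimConfig.__dataclass_fields__.values()} | {"sweeps", "polygenic"},
        "urbscore": {"concentration"},
        "structure": {"vif_threshold", "window_snps", "step_snps"},
        "gea": {"K", "fdr", "db_threshold", "intersection_reps"},
        "scan": {"maf_min", "cutoff", "max_gap", "rsb_threshold", "xpnsl_threshold"},
        "windows": {"size", "step", "percentile", "min_snps", "merge_gap"},
        "share": {"reps"},
    }

    @classmethod
    def from_dict(cls, d):
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for sub, allowed in cls._KNOWN_SUB.items():
            bad = set(d.get(sub, {})) - allowed
            if bad:
                raise ValueError(f"unknown keys in '{sub}' block: {sorted(bad)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _stage_seed(global_seed, stage):
    # counter-based expansion; keep derived seeds below 2**31
    ss = np.random.SeedSequence([int(global_seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _digest(path):
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config, out_dir=None):
    """Run all stages; returns (manifest, results dict).

    Rerunning with the same config and seed reproduces byte-identical
    TSV/BED outputs.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    results = {}

    def record(stage, t0, outputs):
        manifest.append(
            dict(stage=stage, seed=_stage_seed(cfg.seed, stage),
                 wall_time_s=round(time.time() - t0, 3),
                 outputs={str(p.name): _digest(p) for p in outputs})
        )

    # ---- simulate --------------------------------------------------------
    t0 = time.time()
    log.info("stage simulate")
    sim_kwargs = dict(cfg.sim)
    sweeps = [SweepSpec(**s) for s in sim_kwargs.pop("sweeps", [])]
    poly = [PolygenicLocus(**p) for p in sim_kwargs.pop("polygenic", [])]
    sim_kwargs.pop("seed", None)
    sim = SimConfig(seed=_stage_seed(cfg.seed, "simulate"), sweeps=sweeps,
                    polygenic=poly, **sim_kwargs)
    panel, samples, truth = simulate_panel(sim)
    sites = generate_sites(sim.n_localities, seed=_stage_seed(cfg.seed, "simulate"))
    vcf_path = out / "panel.vcf"
    uio.write_phased_vcf(panel, vcf_path, chrom_lengths=sim.chrom_lengths)
    uio.write_samples(samples, out / "samples.tsv")
    uio.write_sites(sites, out / "sites.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    uio.write_chrom_table(sim.chrom_class(), sim.chrom_lengths, out / "chroms.tsv")
    results.update(panel=panel, samples=samples, truth=truth, sites=sites, sim=sim)
    record("simulate", t0, [vcf_path, out / "samples.tsv", out / "truth.tsv"])

    # ---- urbanisation score ---------------------------------------------
    t0 = time.time()
    log.info("stage urbscore")
    lc = generate_landcover(sites, sites["urban_intensity"].to_numpy(),
                            seed=_stage_seed(cfg.seed, "urbscore"),
                            **cfg.urbscore)
    uio.write_landcover(lc, out / "landcover.csv")
    score = score_urbanisation(lc)
    score.to_csv(out / "urbscore.tsv", sep="\t", index=False,
                 float_format="%.12g")
    env = {}
    for _, row in sites.iterrows():
        v = float(score.loc[score["site_id"] == row["site_id"], "pc_urb"].iloc[0])
        env[(row["locality"], row["habitat"])] = v
    results.update(landcover=lc, urbscore=score, env=env)
    record("urbscore", t0, [out / "landcover.csv", out / "urbscore.tsv"])

    # ---- structure -------------------------------------------------------
    t0 = time.time()
    log.info("stage structure")
    pops = samples.populations()
    he = pd.DataFrame(
        [dict(population=population_label(*p),
              He=expected_heterozygosity(panel, samples, *p)) for p in pops]
    )
    he.to_csv(out / "heterozygosity.tsv", sep="\t", index=False,
              float_format="%.12g")
    labels = [population_label(*p) for p in pops]
    fst = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(pops):
        for j in range(i + 1, len(pops)):
            v = wc_fst(panel, samples, a, pops[j]).pair_mean
            fst.iloc[i, j] = fst.iloc[j, i] = v
    fst.to_csv(out / "fst_matrix.tsv", sep="\t", float_format="%.12g")
    pruned = ld_prune(panel, **cfg.structure)
    np.savetxt(out / "pruned_snps.tsv", pruned, fmt="%d")
    results.update(he=he, fst=fst, pruned=pruned)
    record("structure", t0, [out / "heterozygosity.tsv", out / "fst_matrix.tsv"])

    # ---- gea -------------------------------------------------------------
    t0 = time.time()
    log.info("stage gea")
    gea_cfg = dict(K=4, fdr=0.01, db_threshold=20.0, intersection_reps=10_000)
    gea_cfg.update(cfg.gea)
    env_ind = env_to_individuals(samples, env)
    lf = latent_factor_gea(panel, env_ind, K=gea_cfg["K"], fdr=gea_cfg["fdr"])
    cov = covariance_association(panel, samples, env, pruned_snps=pruned,
                                 db_threshold=gea_cfg["db_threshold"])
    core = core_intersection(lf.significant_lfmm, cov.significant_cov,
                             panel.n_sites, reps=gea_cfg["intersection_reps"],
                             seed=_stage_seed(cfg.seed, "gea"))
    gea_tab = lf.to_frame(panel.chrom, panel.pos)
    gea_tab["bf_db"] = cov.bf_db
    gea_tab["significant_cov"] = cov.significant_cov
    uio.write_snp_stats(gea_tab, out / "gea.tsv")
    results.update(lfmm=lf, cov=cov, core=core)
    record("gea", t0, [out / "gea.tsv"])

    # ---- scan ------------------------------------------------------------
    t0 = time.time()
    log.info("stage scan")
    scan_cfg = dict(maf_min=0.05, cutoff=0.05, max_gap=200_000,
                    rsb_threshold=4.0, xpnsl_threshold=2.0)
    scan_cfg.update(cfg.scan)
    scans = {}
    for loc in samples.pairs():
        pu = panel.subset_samples(samples.members(loc, "urban"))
        pr = panel.subset_samples(samples.members(loc, "rural"))
        rsb = rsb_scan(pu, pr, maf_min=scan_cfg["maf_min"],
                       cutoff=scan_cfg["cutoff"], max_gap=scan_cfg["max_gap"],
                       threshold=scan_cfg["rsb_threshold"])
        xp = xpnsl_scan(pu, pr, maf_min=scan_cfg["maf_min"],
                        threshold=scan_cfg["xpnsl_threshold"])
        scans[loc] = dict(rsb=rsb, xpnsl=xp)
        uio.write_snp_stats(rsb.to_frame(), out / f"rsb_{loc}.tsv")
        uio.write_snp_stats(xp.to_frame(), out / f"xpnsl_{loc}.tsv")
    results["scans"] = scans
    record("scan", t0, sorted(out.glob("rsb_*.tsv")))

    # ---- windows ---------------------------------------------------------
    t0 = time.time()
    log.info("stage windows")
    win_cfg = dict(size=200_000, step=50_000, percentile=95.0, min_snps=10,
                   merge_gap=200_000)
    win_cfg.update(cfg.windows)
    skeleton = uwin.make_windows(sim.chrom_lengths, size=win_cfg["size"],
                                 step=win_cfg["step"],
                                 chrom_class=sim.chrom_class())
    regions_by_pop = {}
    for loc, sc in scans.items():
        merged = []
        for stat_name, thr in (("rsb", scan_cfg["rsb_threshold"]),
                               ("xpnsl", scan_cfg["xpnsl_threshold"])):
            res = sc[stat_name]
            snp_stats = pd.DataFrame(
                {"chrom": res.chrom, "pos": res.pos, "stat": res.score}
            )
            wt = uwin.summarise_in_windows(snp_stats, skeleton, thr,
                                           min_snps=win_cfg["min_snps"])
            flags = uwin.dual_criterion_outliers(wt, percentile=win_cfg["percentile"])
            reg = uwin.merge_regions(wt, flags, max_gap=win_cfg["merge_gap"])
            uio.write_regions(reg, out / f"regions_{stat_name}_{loc}.bed")
            merged.append(reg)
        regions_by_pop[loc] = pd.concat(merged, ignore_index=True)
    results["regions"] = regions_by_pop
    record("windows", t0, sorted(out.glob("regions_*.bed")))

    # ---- share -----------------------------------------------------------
    t0 = time.time()
    log.info("stage share")
    share_cfg = dict(reps=100_000)
    share_cfg.update(cfg.share)
    genes = _genes_from_panel(panel, sim.chrom_lengths)
    gene_sets = ush.genes_under_selection(regions_by_pop, genes)
    universe = list(genes["gene_id"])
    null = ush.sharing_null(gene_sets, universe, reps=share_cfg["reps"],
                            seed=_stage_seed(cfg.seed, "share"))
    null.to_csv(out / "sharing_null.tsv", sep="\t", index=False,
                float_format="%.12g")
    results.update(gene_sets=gene_sets, sharing=null, genes=genes)
    record("share", t0, [out / "sharing_null.tsv"])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest, results


def _genes_from_panel(panel, chrom_lengths, gene_size=40_000, spacing=100_000):
    """Regular synthetic gene grid over the simulated chromosomes."""
    rows = []
    k = 0
    for c, L in chrom_lengths.items():
        start = 10_000
        while start + gene_size < L:
            k += 1
            rows.append(dict(gene_id=f"g{k:05d}", chrom=c, start=start,
                             end=start + gene_size, strand="+", introns=[]))
            start += spacing
    return pd.DataFrame(rows)
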