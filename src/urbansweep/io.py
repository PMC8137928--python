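"""Readers and writers for the standard formats the pipeline touches.

VCFv4.2 (phased GT) for haplotypes, GFF3/BED for gene annotation, TSV
sidecars for samples, sites and chromosome classes, CSV for land cover,
BED for merged outlier regions. Coordinate conventions are those of
:mod:`urbansweep.panel`: 1-based SNP positions, 0-based half-open intervals.
"""

from __future__ import annotations

import io as _io
import os

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import HaplotypePanel, SampleFrame

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "read_gene_annotation",
    "read_chrom_table",
    "read_samples",
    "write_samples",
    "read_sites",
    "write_sites",
    "read_landcover",
    "write_landcover",
    "write_snp_stats",
    "read_snp_stats",
    "write_regions",
    "read_regions",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(path, chrom_class=None):
    """Load a phased, biallelic-SNP VCF into a :class:`HaplotypePanel`.

    Fails fast on unphased genotypes, missing calls, multiallelic records
    and non-SNP alleles; the error names the offending record. No silent
    imputation is ever performed.
    """
    vcf = VCF(os.fspath(path))
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    for var in vcf:
        where = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"record {where} is not biallelic (ALT={var.ALT})")
        if len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(f"record {where} is not a SNP ({var.REF}>{var.ALT[0]})")
        gts = var.genotypes  # [[a, b, phased], ...]
        row = np.empty(2 * len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) < 3 or gt[0] < 0 or gt[1] < 0:
                raise ValueError(f"missing genotype call at {where}, sample {samples[i]}")
            if not gt[2]:
                raise ValueError(f"unphased genotype at {where}, sample {samples[i]}")
            row[2 * i] = gt[0]
            row[2 * i + 1] = gt[1]
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(row)
    vcf.close()
    hap = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, 2 * len(samples)), dtype=np.int8)
    )
    return HaplotypePanel(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        haplotypes=hap,
        chrom_class=dict(chrom_class or {}),
    )


def write_phased_vcf(panel, path, chrom_lengths=None):
    """Write a panel as a plain-text VCFv4.2 file with phased GT fields."""
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=urbansweep\n")
    lengths = dict(chrom_lengths or {})
    for c in panel.chromosomes():
        if c in lengths:
            buf.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        else:
            buf.write(f"##contig=<ID={c}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(str(s) for s in panel.sample_ids)
        + "\n"
    )
    h = panel.haplotypes
    for j in range(panel.n_sites):
        gts = "\t".join(
            f"{h[j, 2 * i]}|{h[j, 2 * i + 1]}" for i in range(panel.n_samples)
        )
        buf.write(
            f"{panel.chrom[j]}\t{panel.pos[j]}\t.\t{panel.ref_allele[j]}\t"
            f"{panel.alt_allele[j]}\t.\tPASS\t.\tGT\t{gts}\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def _merge_intervals(ivals):
    out = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_gene_annotation(path):
    """Read gene intervals from GFF3 or BED into a gene table.

    Returns a DataFrame with columns gene_id, chrom, start, end, strand,
    introns — coordinates 0-based half-open. For GFF3, introns are the gaps
    between consecutive exons of each transcript, unioned over the gene's
    transcripts; BED input yields empty intron lists.
    """
    path = os.fspath(path)
    with open(path) as fh:
        head = fh.read(2048)
    is_gff = "##gff" in head or any(
        "\tgene\t" in line or "\tmRNA\t" in line for line in head.splitlines()
    )
    if is_gff:
        return _read_gff3(path)
    return _read_bed_genes(path)


def _read_gff3(path):
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    records = []
    for gene in db.features_of_type("gene", order_by="start"):
        g_start, g_end = gene.start - 1, gene.end  # to half-open
        intron_ivals = []
        for tx in db.children(gene, featuretype=("mRNA", "transcript")):
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(tx, featuretype="exon")
            )
            for s, e in exons:
                if s < g_start or e > g_end:
                    raise ValueError(
                        f"exon [{s},{e}) outside span of gene {gene.id}"
                    )
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 > e1:
                    intron_ivals.append((e1, s2))
        records.append(
            dict(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=g_start,
                end=g_end,
                strand=gene.strand if gene.strand in "+-" else ".",
                introns=_merge_intervals(intron_ivals),
            )
        )
    return _gene_frame(records)


def _read_bed_genes(path):
    records = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {ln}: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"gene{ln}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            records.append(
                dict(gene_id=name, chrom=chrom, start=start, end=end,
                     strand=strand, introns=[])
            )
    return _gene_frame(records)


def _gene_frame(records):
    df = pd.DataFrame(
        records, columns=["gene_id", "chrom", "start", "end", "strand", "introns"]
    )
    if len(df) and not (df["start"] < df["end"]).all():
        bad = df[~(df["start"] < df["end"])].iloc[0]
        raise ValueError(f"gene {bad.gene_id} has start >= end")
    return df


# ---------------------------------------------------------------------------
# TSV / CSV sidecars
# ---------------------------------------------------------------------------

def read_chrom_table(path):
    """Sidecar TSV (chrom, class, length) -> (class dict, length dict)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "class", "length"):
        if col not in df.columns:
            raise ValueError(f"chromosome table missing column {col!r}")
    classes = dict(zip(df["chrom"], df["class"]))
    lengths = dict(zip(df["chrom"], df["length"].astype(int)))
    return classes, lengths


def write_chrom_table(chrom_class, chrom_lengths, path):
    df = pd.DataFrame(
        {
            "chrom": list(chrom_lengths),
            "class": [chrom_class[c] for c in chrom_lengths],
            "length": [chrom_lengths[c] for c in chrom_lengths],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_samples(path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    sf = SampleFrame(df)
    counts = df.groupby(["locality", "habitat"]).size()
    odd = counts[(counts < 10) | (counts > 16)]
    if len(odd):
        import warnings

        warnings.warn(
            f"{len(odd)} population(s) outside the 10-16 individuals-per-site "
            "design range",
            stacklevel=2,
        )
    return sf


def write_samples(samples, path):
    samples.df.to_csv(path, sep="\t", index=False)


def read_sites(path):
    df = pd.read_csv(path, sep="\t")
    need = {"site_id", "locality", "habitat", "longitude", "latitude"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if df.duplicated(["locality", "habitat"]).any():
        raise ValueError("site table must have one record per (locality, habitat)")
    return df


def write_sites(sites, path):
    sites.to_csv(path, sep="\t", index=False)


def read_landcover(path):
    df = pd.read_csv(path)
    need = {"site_id", "cell_id", "p_buildings", "p_vegetation", "p_paved"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"land-cover table missing columns: {sorted(missing)}")
    total = df[["p_buildings", "p_vegetation", "p_paved"]].sum(axis=1)
    if (total > 1 + 1e-9).any():
        raise ValueError("cover proportions sum to more than 1 in some cells")
    return df


def write_landcover(df, path):
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def _check_sortable_chroms(chroms):
    kinds = {type(c) for c in chroms}
    if len(kinds) > 1:
        raise ValueError(
            f"mixed chromosome naming types {sorted(k.__name__ for k in kinds)}; "
            "cannot order records"
        )


def write_snp_stats(table, path):
    """Write a per-SNP statistics table as TSV, deterministic column order.

    chrom and pos lead; remaining columns in sorted name order. Floats are
    written with 12 significant digits so a write-read round trip preserves
    values to that precision.
    """
    df = pd.DataFrame(table)
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise ValueError("snp stat table requires chrom and pos columns")
    _check_sortable_chroms(df["chrom"].tolist())
    rest = sorted(c for c in df.columns if c not in ("chrom", "pos"))
    df = df[["chrom", "pos"] + rest]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_snp_stats(path):
    return pd.read_csv(path, sep="\t")


def write_regions(regions, path):
    """Write merged outlier regions as BED (0-based half-open)."""
    df = pd.DataFrame(regions)
    cols = ["chrom", "start", "end"]
    if df.empty:
        with open(path, "w") as fh:
            fh.write("")
        return
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"region table missing column {c!r}")
    _check_sortable_chroms(df["chrom"].tolist())
    df = df.sort_values(["chrom", "start"])
    extra = [c for c in ("name", "n_windows", "peak_stat") if c in df.columns]
    with open(path, "w") as fh:
        for _, r in df.iterrows():
            fields = [str(r["chrom"]), str(int(r["start"])), str(int(r["end"]))]
            fields += [f"{r[c]:.12g}" if isinstance(r[c], float) else str(r[c]) for c in extra]
            fh.write("\t".join(fields) + "\n")


def read_regions(path):
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            rows.append(dict(chrom=parts[0], start=int(parts[1]), end=int(parts[2])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
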