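"""Core in-memory data model: phased haplotype panels and sample metadata.

Conventions used throughout the package:

* SNP positions are 1-based physical coordinates (bp), strictly increasing
  within each chromosome.
* All intervals (windows, genes, merged regions) are 0-based half-open.
  A 1-based SNP position ``p`` falls in interval ``[start, end)`` iff
  ``p - 1`` is in ``[start, end)``.
* Haplotype allele code 1 is always the ALT allele; minor/major status is
  computed per population at use time and never stored.
* Chromosomes are classified as ``"autosome"`` or ``"Z"`` via an explicit
  sidecar table, never guessed from names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOME = "autosome"
Z = "Z"

_VALID_CLASSES = frozenset({AUTOSOME, Z})


def pos_to_interval_index(pos):
    """Map 1-based SNP positions to the 0-based coordinate used for intervals."""
    return np.asarray(pos) - 1


def interval_contains_pos(start, end, pos):
    """True iff the 1-based position ``pos`` lies in half-open ``[start, end)``."""
    p0 = pos - 1
    return (p0 >= start) & (p0 < end)


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes for a set of diploid samples.

    ``haplotypes`` has shape (n_sites, 2 * n_samples); columns ``2i`` and
    ``2i + 1`` are the two phased haplotypes of sample ``i`` in
    ``sample_ids`` order. Entries are strictly 0 (REF) or 1 (ALT); panels
    with missing calls are rejected at load time.
    """

    sample_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    haplotypes: np.ndarray
    chrom_class: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self):
        n_sites = len(self.pos)
        if self.haplotypes.shape != (n_sites, 2 * len(self.sample_ids)):
            raise ValueError(
                f"haplotype matrix shape {self.haplotypes.shape} does not match "
                f"{n_sites} sites x 2*{len(self.sample_ids)} samples"
            )
        if n_sites and not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must all be 0 or 1 (no missingness)")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")
        for c, cls in self.chrom_class.items():
            if cls not in _VALID_CLASSES:
                raise ValueError(f"unknown chromosome class {cls!r} for {c}")

    # -- basic shape ------------------------------------------------------
    @property
    def n_sites(self):
        return len(self.pos)

    @property
    def n_samples(self):
        return len(self.sample_ids)

    @property
    def n_haplotypes(self):
        return self.haplotypes.shape[1]

    def chromosomes(self):
        """Chromosome labels in order of first appearance."""
        return list(pd.unique(self.chrom)) if self.n_sites else []

    def class_of(self, chrom):
        try:
            return self.chrom_class[chrom]
        except KeyError:
            raise KeyError(
                f"chromosome {chrom!r} has no autosome/Z class; supply a chromosome table"
            ) from None

    def site_classes(self):
        """Per-site chromosome class array."""
        return np.array([self.class_of(c) for c in self.chrom], dtype=object)

    # -- views ------------------------------------------------------------
    def sample_index(self, sample_ids):
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} not in panel") from None

    def subset_samples(self, sample_ids):
        """Panel restricted to the given samples (order as given)."""
        idx = self.sample_index(sample_ids)
        cols = np.empty(2 * len(idx), dtype=np.intp)
        cols[0::2] = 2 * idx
        cols[1::2] = 2 * idx + 1
        return HaplotypePanel(
            sample_ids=list(sample_ids),
            chrom=self.chrom,
            pos=self.pos,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            haplotypes=self.haplotypes[:, cols],
            chrom_class=dict(self.chrom_class),
        )

    def take_sites(self, mask_or_index):
        sel = np.asarray(mask_or_index)
        return HaplotypePanel(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[sel],
            pos=self.pos[sel],
            ref_allele=self.ref_allele[sel],
            alt_allele=self.alt_allele[sel],
            haplotypes=self.haplotypes[sel],
            chrom_class=dict(self.chrom_class),
        )

    def sites_on(self, chrom):
        """Boolean site mask for one chromosome."""
        return np.asarray(self.chrom == chrom)

    # -- derived matrices -------------------------------------------------
    def dosages(self):
        """(n_sites, n_samples) ALT-dosage matrix (0/1/2)."""
        h = self.haplotypes
        return (h[:, 0::2] + h[:, 1::2]).astype(np.int8)

    def alt_freq(self, sample_idx=None):
        """Per-site ALT allele frequency, optionally over a sample subset."""
        h = self.haplotypes
        if sample_idx is not None:
            idx = np.asarray(sample_idx, dtype=np.intp)
            cols = np.empty(2 * len(idx), dtype=np.intp)
            cols[0::2] = 2 * idx
            cols[1::2] = 2 * idx + 1
            h = h[:, cols]
        if h.shape[1] == 0:
            raise ValueError("allele frequency over zero haplotypes")
        return h.mean(axis=1)


@dataclass
class SampleFrame:
    """Per-individual metadata: locality, habitat ({urban, rural}) and sex.

    A population is a (locality, habitat) combination; a locality present
    with both habitats forms an urban-rural pair.
    """

    df: pd.DataFrame

    REQUIRED = ("individual", "locality", "habitat", "sex")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample table missing columns: {missing}")
        bad = set(self.df["habitat"]) - {"urban", "rural"}
        if bad:
            raise ValueError(f"unknown habitat labels: {sorted(bad)}")
        if self.df["individual"].duplicated().any():
            raise ValueError("duplicate individual ids in sample table")

    def __len__(self):
        return len(self.df)

    def populations(self):
        """(locality, habitat) combinations present, sorted."""
        return sorted(set(zip(self.df["locality"], self.df["habitat"])))

    def pairs(self):
        """Localities sampled in both habitats, sorted."""
        by_loc = self.df.groupby("locality")["habitat"].agg(set)
        return sorted(loc for loc, habs in by_loc.items() if {"urban", "rural"} <= habs)

    def members(self, locality, habitat):
        sel = (self.df["locality"] == locality) & (self.df["habitat"] == habitat)
        ids = list(self.df.loc[sel, "individual"])
        if not ids:
            raise KeyError(f"no samples for population ({locality!r}, {habitat!r})")
        return ids

    def population_of(self, individual):
        row = self.df[self.df["individual"] == individual]
        if row.empty:
            raise KeyError(f"unknown individual {individual!r}")
        r = row.iloc[0]
        return (r["locality"], r["habitat"])


def population_label(locality, habitat):
    return f"{locality}_{habitat}"
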