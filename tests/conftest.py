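import numpy as np
import pandas as pd
import pytest

from urbansweep.panel import HaplotypePanel, SampleFrame


def make_panel(haps, pos=None, chrom=None, chrom_class=None, sample_prefix="s"):
    """Build a small panel from a (sites x haplotypes) 0/1 array."""
    haps = np.asarray(haps, dtype=np.int8)
    n_sites, n_hap = haps.shape
    assert n_hap % 2 == 0
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 1000
    if chrom is None:
        chrom = ["chr1"] * n_sites
    classes = chrom_class or {c: "autosome" for c in set(chrom)}
    return HaplotypePanel(
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_hap // 2)],
        chrom=np.array(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref_allele=np.array(["A"] * n_sites, dtype=object),
        alt_allele=np.array(["T"] * n_sites, dtype=object),
        haplotypes=haps,
        chrom_class=classes,
    )


def make_samples(spec):
    """spec: list of (individual, locality, habitat) or (ind, loc, hab, sex)."""
    rows = []
    for entry in spec:
        ind, loc, hab = entry[:3]
        sex = entry[3] if len(entry) > 3 else "unknown"
        rows.append(dict(individual=ind, locality=loc, habitat=hab, sex=sex))
    return SampleFrame(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One shared small 2-locality forward simulation for structural tests."""
    from urbansweep.simulate import SimConfig, simulate_panel

    cfg = SimConfig(
        n_localities=2, n_sites_target=400,
        chrom_lengths={"chr1": 3_000_000, "chrZ": 1_500_000}, z_chroms=("chrZ",),
        N_anc=80, N_rural=40, N_urban=40, founder_size=20,
        t_burnin=10, t_split=15, t_urban=12, seed=42,
    )
    return simulate_panel(cfg) + (cfg,)
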