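import numpy as np
import pandas as pd
import pytest

from urbansweep.sharing import (decompose_effects, genes_under_selection,
                                overrepresentation, pc_level_decomposition,
                                shared_sets_vs_distance, sharing_null,
                                shift_summary)

from conftest import make_panel, make_samples
from oracles import eta2_type2, hypergeom_tail


def panel_from_dosages(dos_by_pop):
    """dos_by_pop: list of (locality, habitat, snps x individuals dosages)."""
    blocks, spec = [], []
    k = 0
    for loc, hab, dos in dos_by_pop:
        dos = np.asarray(dos)
        h = np.zeros((dos.shape[0], 2 * dos.shape[1]), dtype=np.int8)
        h[:, 0::2] = (dos >= 1)
        h[:, 1::2] = (dos == 2)
        blocks.append(h)
        for i in range(dos.shape[1]):
            spec.append((f"s{k}", loc, hab))
            k += 1
    return make_panel(np.hstack(blocks)), make_samples(spec)


class TestDecomposeEffects:
    def test_worked_example_eta2_half_zero_zero(self):
        """Rural cells {0,1}, urban cells {1,2} in both localities."""
        panel, samples = panel_from_dosages([
            ("L1", "rural", [[0, 1]]), ("L1", "urban", [[1, 2]]),
            ("L2", "rural", [[0, 1]]), ("L2", "urban", [[1, 2]]),
        ])
        out = decompose_effects(panel, samples)
        row = out.iloc[0]
        assert row.eta2_habitat == pytest.approx(0.5, abs=1e-10)
        assert row.eta2_locality == pytest.approx(0.0, abs=1e-10)
        assert row.eta2_interaction == pytest.approx(0.0, abs=1e-10)
        assert row.consistent

    def test_opposite_shifts_load_on_interaction(self):
        """Urban +delta in one locality, -delta in the other."""
        panel, samples = panel_from_dosages([
            ("L1", "rural", [[0, 0, 1, 1]]), ("L1", "urban", [[1, 1, 2, 2]]),
            ("L2", "rural", [[1, 1, 2, 2]]), ("L2", "urban", [[0, 0, 1, 1]]),
        ])
        row = decompose_effects(panel, samples).iloc[0]
        assert row.eta2_interaction > row.eta2_habitat
        assert not row.consistent

    def test_constant_dosage_snp_skipped(self):
        panel, samples = panel_from_dosages([
            ("L1", "rural", [[1, 1], [0, 1]]), ("L1", "urban", [[1, 1], [1, 2]]),
            ("L2", "rural", [[1, 1], [0, 2]]), ("L2", "urban", [[1, 1], [1, 1]]),
        ])
        out = decompose_effects(panel, samples)
        assert out.attrs["n_skipped"] == 1
        assert len(out) == 1

    def test_matches_projection_glm_oracle_on_random_fixtures(self, rng):
        for _ in range(15):
            dos_by_pop = []
            for loc in ("L1", "L2", "L3"):
                for hab in ("urban", "rural"):
                    n = int(rng.integers(3, 7))
                    dos_by_pop.append((loc, hab, rng.integers(0, 3, (2, n))))
            panel, samples = panel_from_dosages(dos_by_pop)
            out = decompose_effects(panel, samples)
            hab = samples.df["habitat"].to_numpy()
            loc = samples.df["locality"].to_numpy()
            dos = panel.dosages()
            for _, row in out.iterrows():
                expected = eta2_type2(dos[int(row.snp)].astype(float), hab, loc)
                assert row.eta2_habitat == pytest.approx(expected["habitat"], abs=1e-8)
                assert row.eta2_locality == pytest.approx(expected["locality"], abs=1e-8)
                assert row.eta2_interaction == pytest.approx(
                    expected["interaction"], abs=1e-8
                )


class TestPcLevelDecomposition:
    def test_uniform_urban_shift_loads_pc1_on_habitat(self, rng):
        dos_by_pop = []
        for loc in ("L1", "L2", "L3"):
            base = rng.integers(0, 2, (40, 1))
            rural = np.clip(base + rng.integers(0, 2, (40, 8)) - 0, 0, 2)
            urban = np.clip(rural[:, :8] + 1, 0, 2)  # uniform +1 shift
            dos_by_pop.append((loc, "rural", rural))
            dos_by_pop.append((loc, "urban", urban))
        panel, samples = panel_from_dosages(dos_by_pop)
        out = pc_level_decomposition(panel, samples, np.arange(40), n_axes=2)
        pc1 = out[out.axis == 1].iloc[0]
        assert pc1.eta2_habitat > pc1.eta2_interaction

    def test_axes_beyond_rank_error(self, rng):
        panel, samples = panel_from_dosages([
            ("L1", "rural", rng.integers(0, 3, (3, 2))),
            ("L1", "urban", rng.integers(0, 3, (3, 2))),
        ])
        with pytest.raises(ValueError):
            pc_level_decomposition(panel, samples, np.arange(3), n_axes=4)

    def test_invariant_to_sample_order(self, rng):
        dos_by_pop = [
            ("L1", "rural", rng.integers(0, 3, (10, 5))),
            ("L1", "urban", rng.integers(0, 3, (10, 5))),
            ("L2", "rural", rng.integers(0, 3, (10, 5))),
            ("L2", "urban", rng.integers(0, 3, (10, 5))),
        ]
        panel, samples = panel_from_dosages(dos_by_pop)
        out1 = pc_level_decomposition(panel, samples, np.arange(10), n_axes=2)
        perm = rng.permutation(panel.n_samples)
        ids = [panel.sample_ids[i] for i in perm]
        panel2 = panel.subset_samples(ids)
        from urbansweep.panel import SampleFrame

        df2 = samples.df.set_index("individual").loc[ids].reset_index()
        out2 = pc_level_decomposition(panel2, SampleFrame(df2),
                                      np.arange(10), n_axes=2)
        np.testing.assert_allclose(out1.eta2_habitat, out2.eta2_habitat, atol=1e-8)


class TestShiftSummary:
    def test_unanimous_minor_allele(self):
        dos_by_pop = []
        for i in range(9):
            dos_by_pop.append((f"L{i+1}", "urban", [[0, 0, 0, 0, 1]]))  # p=0.1
            dos_by_pop.append((f"L{i+1}", "rural", [[0, 0, 1, 1, 2]]))
        panel, samples = panel_from_dosages(dos_by_pop)
        out = shift_summary(panel, samples)
        assert out.iloc[0]["n_concordant"] == 9

    def test_alternating_frequencies_count_low_side(self):
        dos_by_pop = []
        for i in range(9):
            p_low = i % 2 == 0  # 5 pops at 0.1, 4 at 0.9
            urban = [[0, 0, 0, 0, 1]] if p_low else [[2, 2, 2, 2, 1]]
            dos_by_pop.append((f"L{i+1}", "urban", urban))
            dos_by_pop.append((f"L{i+1}", "rural", [[1, 1, 1, 1, 1]]))
        panel, samples = panel_from_dosages(dos_by_pop)
        out = shift_summary(panel, samples)
        # pooled ALT freq 0.456 -> global minor = ALT; local minor = ALT only
        # where local freq 0.1
        assert out.iloc[0]["n_concordant"] == 5

    def test_delta_af_arithmetic(self):
        panel, samples = panel_from_dosages([
            ("L1", "urban", [[0, 0, 1, 1, 0]]),   # p = 0.2
            ("L1", "rural", [[2, 2, 1, 1, 1]]),   # p = 0.7
        ])
        out = shift_summary(panel, samples)
        assert out.iloc[0]["daf_L1"] == pytest.approx(0.5)


class TestGenesUnderSelection:
    GENES = pd.DataFrame([
        dict(gene_id="gA", chrom="chr1", start=100_000, end=150_000,
             strand="+", introns=[]),
        dict(gene_id="gB", chrom="chr1", start=340_000, end=400_000,
             strand="+", introns=[]),
    ])

    def test_overlap_flags_gene(self):
        regions = {"pop1": pd.DataFrame([
            dict(chrom="chr1", start=140_000, end=340_000)
        ])}
        out = genes_under_selection(regions, self.GENES)
        assert out["pop1"] == {"gA"}

    def test_half_open_abutment_does_not_flag(self):
        regions = {"pop1": pd.DataFrame([
            dict(chrom="chr1", start=150_000, end=340_000)
        ])}
        out = genes_under_selection(regions, self.GENES)
        assert out["pop1"] == set()

    def test_agrees_with_all_pairs_oracle(self, rng):
        genes = pd.DataFrame([
            dict(gene_id=f"g{i}", chrom="chr1",
                 start=int(s), end=int(s) + int(rng.integers(1_000, 80_000)),
                 strand="+", introns=[])
            for i, s in enumerate(rng.choice(np.arange(0, 10**6, 500), 40, False))
        ])
        regions = pd.DataFrame([
            dict(chrom="chr1", start=int(s), end=int(s) + int(rng.integers(10_000, 200_000)))
            for s in rng.choice(np.arange(0, 10**6, 1000), 8, False)
        ])
        got = genes_under_selection({"p": regions}, genes)["p"]
        brute = {
            g.gene_id
            for _, g in genes.iterrows()
            for _, r in regions.iterrows()
            if g.start < r.end and r.start < g.end
        }
        assert got == brute


class TestSharingNull:
    def test_closed_form_two_population_mean(self):
        """E[shared] = G * (1 - (1 - 1/G)^n)^2 for two sets of n draws."""
        G, n = 100, 10
        universe = [f"g{i}" for i in range(G)]
        sets = {"a": set(universe[:n]), "b": set(universe[n:2 * n])}
        out = sharing_null(sets, universe, reps=20_000, seed=0)
        expected = G * (1 - (1 - 1 / G) ** n) ** 2
        assert out[out.k == 2].null_mean.iloc[0] == pytest.approx(expected, rel=0.05)

    def test_saturated_sets_observed_maximal(self):
        universe = [f"g{i}" for i in range(30)]
        sets = {p: set(universe) for p in ("a", "b", "c")}
        out = sharing_null(sets, universe, reps=500, seed=0)
        assert (out.observed == 30).all()
        assert (out.p <= 0.01).all()

    def test_zero_reps_errors(self):
        with pytest.raises(ValueError, match="reps"):
            sharing_null({"a": set()}, ["g1"], reps=0)

    def test_set_outside_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            sharing_null({"a": {"gX"}}, ["g1", "g2"], reps=10)


class TestSharedSetsVsDistance:
    def test_constructed_perfect_correlation(self, rng):
        x = rng.random((5, 1))
        geo = np.abs(x - x.T)
        shared = geo.max() - geo  # similarity = negated distance
        np.fill_diagonal(shared, shared.max())
        gen = rng.random((5, 5))
        gen = (gen + gen.T) / 2
        np.fill_diagonal(gen, 0)
        out = shared_sets_vs_distance(shared, gen, geo, n_perm=99, seed=0)
        assert out["geographic"].r == pytest.approx(1.0)

    def test_constant_sharing_errors(self):
        shared = np.full((4, 4), 3.0)
        d = np.abs(np.arange(4)[:, None] - np.arange(4)[None]).astype(float)
        with pytest.raises(ValueError, match="constant"):
            shared_sets_vs_distance(shared, d, d)


class TestOverrepresentation:
    def test_term_equal_to_geneset_is_top_hit(self):
        universe = [f"g{i}" for i in range(100)]
        geneset = set(universe[:5])
        annotation = {g: ["T1"] for g in universe[:5]}
        annotation.update({g: ["T2"] for g in universe[5:]})
        out = overrepresentation(geneset, annotation, universe)
        t1 = out[out.term == "T1"].iloc[0]
        assert t1.significant
        assert t1.p == pytest.approx(hypergeom_tail(5, 100, 5, 5), rel=1e-9)

    def test_disjoint_term_p_is_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = overrepresentation(set(universe[:5]),
                                 {g: ["T"] for g in universe[10:]}, universe)
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_exact_tail_enumeration_example(self):
        """Universe 20, term 5, geneset 5, overlap 3."""
        universe = [f"g{i}" for i in range(20)]
        term_genes = universe[:5]
        geneset = set(universe[2:7])  # overlap {g2, g3, g4} = 3
        out = overrepresentation(geneset, {g: ["T"] for g in term_genes}, universe)
        assert out.iloc[0].overlap == 3
        assert out.iloc[0].p == pytest.approx(hypergeom_tail(3, 20, 5, 5), rel=1e-12)

    def test_empty_geneset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            overrepresentation(set(), {"g1": ["T"]}, ["g1"])
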