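import numpy as np
import pandas as pd
import pytest

from urbansweep.popstruct import (expected_heterozygosity, fst_permutation_test,
                                  genotype_pca, haversine_km, ibd_by_habitat,
                                  ld_prune, mantel_test, thin_snps, wc_fst)

from conftest import make_panel, make_samples
from oracles import vif_prune_exhaustive, wc_theta_scalar


def two_pop_panel(dosA, dosB):
    """Panel from per-population dosage lists (snps x individuals)."""
    dosA = np.asarray(dosA)
    dosB = np.asarray(dosB)

    def dos_to_haps(d):
        h = np.zeros((d.shape[0], 2 * d.shape[1]), dtype=np.int8)
        h[:, 0::2] = (d >= 1).astype(np.int8)
        h[:, 1::2] = (d == 2).astype(np.int8)
        return h

    haps = np.hstack([dos_to_haps(dosA), dos_to_haps(dosB)])
    panel = make_panel(haps)
    spec = [(f"s{i}", "A", "urban") for i in range(dosA.shape[1])] + [
        (f"s{i + dosA.shape[1]}", "B", "rural") for i in range(dosB.shape[1])
    ]
    return panel, make_samples(spec)


class TestHeterozygosity:
    def test_monomorphic_panel_gives_zero(self):
        panel, samples = two_pop_panel([[0, 0, 0]], [[0, 0, 0]])
        assert expected_heterozygosity(panel, samples, "A", "urban") == 0.0

    def test_p_half_gives_maximum(self):
        panel, samples = two_pop_panel([[0, 1, 2, 1]], [[0, 0, 0, 0]])
        assert expected_heterozygosity(panel, samples, "A", "urban") == pytest.approx(0.5)

    def test_three_snp_toy_value(self):
        """p = (0.1, 0.5, 0.9) -> He = mean(0.18, 0.5, 0.18) = 0.286667."""
        dosA = np.array([
            [1, 0, 0, 0, 0],   # p = 0.1
            [2, 2, 1, 0, 0],   # p = 0.5
            [2, 2, 2, 2, 1],   # p = 0.9
        ])
        panel, samples = two_pop_panel(dosA, np.zeros((3, 2), dtype=int))
        he = expected_heterozygosity(panel, samples, "A", "urban")
        assert he == pytest.approx(np.mean([0.18, 0.5, 0.18]), abs=1e-12)


class TestWcFst:
    def test_identical_sample_sets_give_zero_pair_mean(self):
        dos = np.array([[0, 1, 2, 1], [1, 1, 0, 2]])
        panel, samples = two_pop_panel(dos, dos)
        res = wc_fst(panel, samples, ("A", "urban"), ("B", "rural"))
        assert (res.theta[~np.isnan(res.theta)] <= 1e-12).all()
        assert res.pair_mean == 0.0

    def test_fixed_difference_gives_one(self):
        panel, samples = two_pop_panel(
            np.full((1, 10), 2), np.zeros((1, 10), dtype=int)
        )
        res = wc_fst(panel, samples, ("A", "urban"), ("B", "rural"))
        assert res.theta[0] == pytest.approx(1.0, abs=1e-9)

    def test_toy_counts_match_scalar_oracle(self):
        """popA 0/0,0/1,1/1,1/1 vs popB 0/0,0/0,0/1,0/1."""
        panel, samples = two_pop_panel([[0, 1, 2, 2]], [[0, 0, 1, 1]])
        res = wc_fst(panel, samples, ("A", "urban"), ("B", "rural"))
        assert res.theta[0] == pytest.approx(
            wc_theta_scalar([0, 1, 2, 2], [0, 0, 1, 1]), abs=1e-12
        )

    def test_symmetric_in_population_order(self, rng):
        dosA = rng.integers(0, 3, size=(30, 6))
        dosB = rng.integers(0, 3, size=(30, 5))
        panel, samples = two_pop_panel(dosA, dosB)
        ab = wc_fst(panel, samples, ("A", "urban"), ("B", "rural"))
        ba = wc_fst(panel, samples, ("B", "rural"), ("A", "urban"))
        np.testing.assert_array_equal(ab.theta, ba.theta)
        assert ab.pair_mean == ba.pair_mean <= 1.0

    def test_monomorphic_snps_excluded_and_counted(self):
        panel, samples = two_pop_panel([[0], [2]] , [[0], [2]])
        # need >=2 per pop: widen
        panel, samples = two_pop_panel(
            [[0, 0], [2, 2], [1, 0]], [[0, 0], [2, 2], [0, 1]]
        )
        res = wc_fst(panel, samples, ("A", "urban"), ("B", "rural"))
        assert res.n_monomorphic == 2
        assert np.isnan(res.theta[0]) and np.isnan(res.theta[1])


class TestFstPermutation:
    def test_fixed_difference_panel_gives_minimal_p(self):
        panel, samples = two_pop_panel(
            np.full((5, 8), 2), np.zeros((5, 8), dtype=int)
        )
        res = fst_permutation_test(panel, samples, ("A", "urban"), ("B", "rural"),
                                   n_perm=99, seed=0)
        assert res.perm_p == pytest.approx(1 / 100)

    def test_deterministic_under_seed(self, rng):
        dosA = rng.integers(0, 3, size=(40, 6))
        dosB = rng.integers(0, 3, size=(40, 6))
        panel, samples = two_pop_panel(dosA, dosB)
        p1 = fst_permutation_test(panel, samples, ("A", "urban"), ("B", "rural"),
                                  n_perm=99, seed=5).perm_p
        p2 = fst_permutation_test(panel, samples, ("A", "urban"), ("B", "rural"),
                                  n_perm=99, seed=5).perm_p
        assert p1 == p2

    def test_thinning_takes_first_snp_per_bin(self):
        panel = make_panel(np.zeros((4, 4)), pos=[1, 40_000, 60_000, 140_000])
        np.testing.assert_array_equal(thin_snps(panel, 50_000), [0, 2, 3])


class TestLdPrune:
    def test_independent_snps_all_retained(self, rng):
        # frequencies away from 0/1; independent draws -> r2 ~ 1/n, VIF ~ 1
        haps = (rng.random((30, 200)) < 0.5).astype(np.int8)
        panel = make_panel(haps)
        kept = ld_prune(panel, window_snps=10, step_snps=5, vif_threshold=2.0)
        assert len(kept) >= 28

    def test_duplicated_snp_loses_exactly_one_copy(self, rng):
        hap_row = (rng.random(20) < 0.5).astype(np.int8)
        other = (rng.random((3, 20)) < 0.5).astype(np.int8)
        haps = np.vstack([hap_row, hap_row, other])
        panel = make_panel(haps)
        kept = set(ld_prune(panel).tolist())
        assert len({0, 1} & kept) == 1

    def test_matches_exhaustive_vif_oracle_on_toys(self, rng):
        """Window-free comparison: one window covering all 5 SNPs."""
        for _ in range(20):
            base = (rng.random((5, 24)) < rng.uniform(0.3, 0.7)).astype(np.int8)
            base[1] = np.where(rng.random(24) < 0.2, 1 - base[0], base[0])
            dosages = base[:, 0::2] + base[:, 1::2]
            panel = make_panel(base)
            kept = ld_prune(panel, window_snps=5, step_snps=5, vif_threshold=2.0)
            expected = vif_prune_exhaustive(dosages.astype(float), 2.0)
            assert kept.tolist() == expected


class TestGenotypePca:
    def test_two_duplicated_clusters_separate_on_pc1(self):
        a = np.tile([0, 0, 1, 1, 0, 1, 1, 0], (6, 1)).T
        b = 1 - a
        haps = np.hstack([np.repeat(a, 1, axis=1), b])
        panel = make_panel(haps)
        scores, pve = genotype_pca(panel, n_components=3)
        pc1 = scores[:, 0]
        left, right = pc1[:3], pc1[3:]
        assert np.ptp(left) < 1e-9 and np.ptp(right) < 1e-9
        assert abs(left[0] - right[0]) > 1e-6

    def test_pve_properties(self, rng):
        haps = (rng.random((40, 16)) < 0.4).astype(np.int8)
        _, pve = genotype_pca(make_panel(haps), n_components=5)
        assert pve.sum() <= 1 + 1e-9
        assert (np.diff(pve) <= 1e-12).all()

    def test_matches_eigendecomposition_oracle(self, rng):
        haps = (rng.random((12, 8)) < 0.5).astype(np.int8)
        panel = make_panel(haps)
        try:
            scores, _ = genotype_pca(panel, n_components=3)
        except ValueError:
            pytest.skip("degenerate random draw")
        dos = panel.dosages().astype(float)
        keep = (dos.std(axis=1) > 0)
        dos = dos[keep]
        p = dos.mean(axis=1) / 2
        X = ((dos - 2 * p[:, None]) / np.sqrt(p * (1 - p))[:, None]).T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(evals)[::-1]
        for axis in range(3):
            expected = evecs[:, order[axis]] * np.sqrt(evals[order[axis]])
            got = scores[:, axis]
            agree = min(np.abs(got - expected).max(), np.abs(got + expected).max())
            assert agree < 1e-8


class TestMantel:
    @staticmethod
    def _dist(rng, n):
        x = rng.random((n, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        return d

    def test_identity_gives_r_one(self, rng):
        d = self._dist(rng, 6)
        res = mantel_test(d, d.copy(), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_toy_matches_direct_upper_triangle_correlation(self, rng):
        a = self._dist(rng, 4)
        b = self._dist(rng, 4)
        res = mantel_test(a, b, n_perm=99, seed=0)
        iu = np.triu_indices(4, 1)
        assert res.r == pytest.approx(np.corrcoef(a[iu], b[iu])[0, 1], abs=1e-12)

    def test_agrees_with_skbio_oracle(self, rng):
        skbio_dist = pytest.importorskip("skbio.stats.distance")
        a = self._dist(rng, 7)
        b = self._dist(rng, 7)
        res = mantel_test(a, b, n_perm=999, seed=1)
        r_skbio, p_skbio, _ = skbio_dist.mantel(
            skbio_dist.DistanceMatrix(a), skbio_dist.DistanceMatrix(b),
            method="pearson", permutations=999, alternative="two-sided",
        )
        assert res.r == pytest.approx(r_skbio, abs=1e-12)
        assert res.p == pytest.approx(p_skbio, abs=0.05)  # MC error only

    def test_constant_matrix_errors(self):
        c = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(c, c, n_perm=99)

    def test_type_one_error_calibrated(self, rng):
        """Shuffled-independent matrices reject at ~alpha."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = self._dist(rng, 7)
            b = self._dist(rng, 7)
            if mantel_test(a, b, n_perm=99, seed=int(rng.integers(2**31))).p <= 0.05:
                rejections += 1
        # binomial 99% CI around 0.05 for 200 draws: [0.014, 0.095]
        assert 0.01 <= rejections / n_rep <= 0.10


class TestIbdByHabitat:
    @staticmethod
    def _sites(n):
        rows = []
        for i in range(n):
            for hab in ("urban", "rural"):
                rows.append(dict(site_id=f"L{i+1}_{hab}", locality=f"L{i+1}",
                                 habitat=hab, longitude=float(i), latitude=45.0))
        return pd.DataFrame(rows)

    def test_distance_built_fst_recovers_positive_r(self):
        sites = self._sites(5)
        labels = [f"L{i+1}_{h}" for i in range(5) for h in ("urban", "rural")]
        geo = haversine_km(sites)
        fst = pd.DataFrame(geo / geo.max() * 0.2, index=labels, columns=labels)
        res = ibd_by_habitat(fst, sites, n_perm=99, seed=0)
        assert res["urban"].r == pytest.approx(1.0)
        assert res["rural"].r == pytest.approx(1.0)

    def test_fewer_than_four_populations_errors(self):
        sites = self._sites(3)
        labels = [f"L{i+1}_{h}" for i in range(3) for h in ("urban", "rural")]
        fst = pd.DataFrame(np.zeros((6, 6)), index=labels, columns=labels)
        with pytest.raises(ValueError, match=">= 4"):
            ibd_by_habitat(fst, sites)

    def test_haversine_known_distance(self):
        # one degree of longitude at the equator ~ 111.19 km on R = 6371 km
        sites = pd.DataFrame(
            [dict(latitude=0.0, longitude=0.0), dict(latitude=0.0, longitude=1.0)]
        )
        d = haversine_km(sites)
        assert d[0, 1] == pytest.approx(6371 * np.pi / 180, rel=1e-6)
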