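import numpy as np
import pytest
from hypothesis import given, strategies as st

from popne.errors import DataError, UndefinedResult
from popne.io import MISSING
from popne.ld import (dosage_r2, em_haplotype_freqs, haplotype_ld,
                      pairwise_ld_scan)

from conftest import make_dataset
from oracles import pair_loglik, pearson_r2_brute


class TestHaplotypeLD:
    def test_complete_ld(self):
        d, dp, r2 = haplotype_ld(0.5, 0.5, 0.5)
        assert (d, dp, r2) == (0.25, 1.0, 1.0)

    def test_linkage_equilibrium(self):
        d, dp, r2 = haplotype_ld(0.2 * 0.3, 0.2, 0.3)
        assert d == pytest.approx(0.0, abs=1e-15)
        assert r2 == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_example(self):
        d, dp, r2 = haplotype_ld(0.10, 0.2, 0.3)
        assert d == pytest.approx(0.04)
        assert r2 == pytest.approx(0.04**2 / (0.16 * 0.21))

    def test_monomorphic_is_undefined(self):
        with pytest.raises(UndefinedResult):
            haplotype_ld(0.5, 1.0, 0.5)

    def test_agrees_with_dosage_r2_on_homozygous_phased_panel(self, rng):
        """When every individual carries two copies of one known gamete,
        dosages are 2x the gamete indicators and both r2 routes coincide."""
        gametes = ["AB", "Ab", "aB", "ab"]
        draws = [gametes[k] for k in rng.integers(0, 4, size=50)]
        dos_a = np.array([2 * (g[0] == "A") for g in draws], dtype=np.int8)
        dos_b = np.array([2 * (g[1] == "B") for g in draws], dtype=np.int8)
        pAB = sum(g == "AB" for g in draws) / len(draws)
        pA = sum(g[0] == "A" for g in draws) / len(draws)
        pB = sum(g[1] == "B" for g in draws) / len(draws)
        _, _, r2_h = haplotype_ld(pAB, pA, pB)
        r2_d, _ = dosage_r2(dos_a, dos_b)
        assert r2_d == pytest.approx(r2_h, abs=1e-12)

    def test_em_route_recovers_known_gamete_frequencies(self):
        """Without double heterozygotes the EM tally equals the true gamete
        frequencies, so the haplotype-route r2 is exact."""
        pairs = [("AB", "AB"), ("AB", "aB"), ("aB", "aB"), ("aB", "ab"),
                 ("ab", "ab"), ("AB", "aB"), ("aB", "ab"), ("aB", "aB")]
        dos_a = np.array([(g1[0] == "A") + (g2[0] == "A") for g1, g2 in pairs],
                         dtype=np.int8)
        dos_b = np.array([(g1[1] == "B") + (g2[1] == "B") for g1, g2 in pairs],
                         dtype=np.int8)
        gam = [g for p in pairs for g in p]
        true = [sum(g == h for g in gam) / len(gam)
                for h in ("AB", "Ab", "aB", "ab")]
        fr = em_haplotype_freqs(dos_a, dos_b)
        np.testing.assert_allclose(list(fr), true, atol=1e-9)
        d_em, dp_em, r2_em = haplotype_ld(fr.pAB, fr.pAB + fr.pAb, fr.pAB + fr.paB)
        d_true, dp_true, r2_true = haplotype_ld(true[0], true[0] + true[1],
                                                true[0] + true[2])
        assert (d_em, dp_em, r2_em) == pytest.approx((d_true, dp_true, r2_true),
                                                     abs=1e-9)


class TestDosageR2:
    def test_self_correlation(self):
        a = np.array([0, 1, 2, 1, 0], dtype=np.int8)
        r2, n = dosage_r2(a, a)
        assert r2 == pytest.approx(1.0)
        assert n == 5

    def test_allele_coding_invariance(self):
        a = np.array([0, 1, 2, 1, 0, 2], dtype=np.int8)
        r2, _ = dosage_r2(a, 2 - a)
        assert r2 == pytest.approx(1.0)

    def test_matches_brute_force_pearson(self):
        a = np.array([0, 1, 2, 2, 1, 0, 1, 2], dtype=np.int8)
        b = np.array([1, 1, 2, 0, 1, 0, 2, 2], dtype=np.int8)
        want, n_want = pearson_r2_brute(a, b)
        got, n_got = dosage_r2(a, b)
        assert got == pytest.approx(want, abs=1e-12)
        assert n_got == n_want

    def test_pairwise_complete_deletion(self):
        a = np.array([0, 1, 2, MISSING, 1], dtype=np.int8)
        b = np.array([0, MISSING, 2, 1, 1], dtype=np.int8)
        _, n = dosage_r2(a, b)
        assert n == 3

    def test_monomorphic_subset_undefined(self):
        a = np.array([1, 1, 1, 0], dtype=np.int8)
        b = np.array([0, 1, 2, MISSING], dtype=np.int8)
        with pytest.raises(UndefinedResult):
            dosage_r2(a, b)

    @given(st.tuples(st.booleans(), st.booleans()),
           st.integers(min_value=0, max_value=2**20))
    def test_coding_flip_property(self, flips, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=30).astype(np.int8)
        b = (a + rng.integers(0, 2, size=30)).clip(0, 2).astype(np.int8)
        fa = (2 - a) if flips[0] else a
        fb = (2 - b) if flips[1] else b
        r2_0, _ = dosage_r2(a, b)
        r2_f, _ = dosage_r2(fa, fb)
        assert r2_f == pytest.approx(r2_0, abs=1e-12)


class TestEMHaplotypes:
    def test_no_double_heterozygotes_equals_direct_tally(self):
        a = np.array([2, 2, 1, 0, 0, 1], dtype=np.int8)
        b = np.array([2, 1, 0, 0, 1, 2], dtype=np.int8)
        fr = em_haplotype_freqs(a, b)
        assert fr.converged
        # direct gamete counting: genotypes resolve unambiguously
        counts = {"AB": 2 + 1 + 1, "Ab": 1 + 1, "aB": 1 + 1, "ab": 2 + 1 + 1}
        total = sum(counts.values())
        assert fr.pAB == pytest.approx(counts["AB"] / total, abs=1e-9)
        assert fr.pab == pytest.approx(counts["ab"] / total, abs=1e-9)

    def test_all_double_heterozygous_symmetric_fixed_point(self):
        a = np.ones(10, dtype=np.int8)
        fr = em_haplotype_freqs(a, a.copy())
        for f in fr:
            assert f == pytest.approx(0.25, abs=1e-9)

    def test_em_beats_grid_search_likelihood(self, rng):
        a = np.array([2, 1, 1, 0, 1, 2, 0, 1, 1, 2], dtype=np.int8)
        b = np.array([1, 1, 0, 0, 1, 2, 1, 2, 1, 0], dtype=np.int8)
        fr = em_haplotype_freqs(a, b)
        tab = np.zeros((3, 3))
        for x, y in zip(a, b):
            tab[x, y] += 1
        pA = fr.pAB + fr.pAb
        pB = fr.pAB + fr.paB
        ll_em = pair_loglik(tab, fr.pAB, pA, pB)
        lo, hi = max(0.0, pA + pB - 1.0), min(pA, pB)
        grid = np.linspace(lo, hi, 100)
        ll_grid = max(pair_loglik(tab, g, pA, pB) for g in grid)
        assert ll_em >= ll_grid - 1e-9

    def test_frequencies_sum_to_one(self, rng):
        a = rng.integers(0, 3, size=25).astype(np.int8)
        b = rng.integers(0, 3, size=25).astype(np.int8)
        fr = em_haplotype_freqs(a, b)
        assert sum(fr) == pytest.approx(1.0, abs=1e-9)


class TestPairwiseScan:
    def test_distance_cap_hand_enumeration(self):
        # adjacent pairs at 100 kb and exactly 500 kb are kept (cap inclusive);
        # the 600 kb outer pair is not
        ds = make_dataset(np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [0, 1, 2]]),
                          positions=[1, 100_001, 600_001])
        pairs = list(pairwise_ld_scan(ds, max_dist_bp=500_000))
        assert [(p.idx_a, p.idx_b) for p in pairs] == [(0, 1), (1, 2)]
        assert pairs[0].dist_bp == 100_000
        assert pairs[1].dist_bp == 500_000

    def test_zero_window_emits_nothing(self, toy_dataset):
        assert list(pairwise_ld_scan(toy_dataset, max_dist_bp=0)) == []

    def test_equally_spaced_closed_form(self, rng):
        m = 12
        calls = rng.integers(0, 3, size=(30, m)).astype(np.int8)
        ds = make_dataset(calls, positions=[100 * (j + 1) for j in range(m)])
        pairs = list(pairwise_ld_scan(ds, max_dist_bp=10_000))
        assert len(pairs) == m * (m - 1) // 2

    def test_matches_brute_force_double_loop(self, rng):
        m, n = 60, 25
        calls = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        calls[rng.random(calls.shape) < 0.05] = MISSING
        chroms = ["1"] * (m // 2) + ["2"] * (m - m // 2)
        pos = sorted(rng.choice(200_000, size=m // 2, replace=False) + 1)
        positions = list(pos) + list(pos)
        ds = make_dataset(calls, chrom=chroms, positions=positions)
        max_d = 80_000
        got = {(p.idx_a, p.idx_b): p for p in pairwise_ld_scan(ds, max_dist_bp=max_d)}
        expected = {}
        for i in range(ds.n_variants):
            for j in range(i + 1, ds.n_variants):
                vi, vj = ds.variants[i], ds.variants[j]
                if vi.chrom != vj.chrom:
                    continue
                d = vj.pos_bp - vi.pos_bp
                if not 0 < d <= max_d:
                    continue
                try:
                    r2, nobs = pearson_r2_brute(ds.calls[:, i], ds.calls[:, j])
                except ZeroDivisionError:
                    continue
                expected[(i, j)] = (r2, nobs, d)
        assert set(got) == set(expected)
        for key, (r2, nobs, d) in expected.items():
            assert got[key].r2 == pytest.approx(r2, abs=1e-12)
            assert got[key].n_obs == nobs
            assert got[key].dist_bp == d
            assert got[key].dist_bp <= max_d

    def test_unsorted_input_rejected(self, rng):
        ds = make_dataset(rng.integers(0, 3, size=(10, 3)).astype(np.int8))
        ds.variants[0], ds.variants[2] = ds.variants[2], ds.variants[0]  # corrupt
        with pytest.raises(DataError, match="sort"):
            list(pairwise_ld_scan(ds))

    def test_dprime_fields_populated(self, rng):
        calls = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        ds = make_dataset(calls)
        pairs = list(pairwise_ld_scan(ds, max_dist_bp=10_000, want_dprime=True))
        assert pairs and all(p.d_prime is None or 0 <= p.d_prime <= 1 for p in pairs)
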