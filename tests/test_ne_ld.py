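import math

import numpy as np
import pytest

from popne.errors import ConfigError, UndefinedResult
from popne.ld import LDPair
from popne.ne_ld import (NeLdConfig, adjust_r2, ne_at_bin, ne_trajectory,
                         physical_to_genetic, sved_feldman_c)
from popne.simulate import expected_r2_sved


class TestDistanceMapping:
    @pytest.mark.parametrize("delta,expected", [
        (1_000_000, 0.01), (0, 0.0), (100_000_000, 1.0)])
    def test_physical_to_genetic(self, delta, expected):
        assert physical_to_genetic(delta, 1e-8) == pytest.approx(expected)

    @pytest.mark.parametrize("d,expected", [
        (0.0, 0.0), (0.1, 0.095), (1.0, 0.5)])
    def test_sved_feldman(self, d, expected):
        assert sved_feldman_c(d) == pytest.approx(expected)

    def test_sved_feldman_bounds(self):
        ds = np.linspace(0, 1, 101)
        cs = np.array([sved_feldman_c(d) for d in ds])
        assert np.all(cs <= ds + 1e-15)
        assert np.all(cs <= 0.5 + 1e-15)
        assert np.all(np.diff(cs) > 0)  # strictly increasing on [0, 1]

    def test_beyond_range_warns(self):
        with pytest.warns(UserWarning):
            sved_feldman_c(1.5)


class TestAdjustR2:
    @pytest.mark.parametrize("r2,n,beta,expected", [
        (0.2, 100, 1, 0.19), (0.2, 100, 2, 0.195)])
    def test_hand_values(self, r2, n, beta, expected):
        assert adjust_r2(r2, n, beta) == pytest.approx(expected)

    def test_exact_zero_at_sampling_floor(self):
        assert adjust_r2(1 / 50, 50, 1) == 0.0


class TestNeAtBin:
    def test_printed_equation_substitution(self):
        t, ne = ne_at_bin(0.2, 0.025)
        assert t == pytest.approx(20.0)
        assert ne == pytest.approx(40.0)

    def test_chained_from_one_megabase(self):
        c = sved_feldman_c(physical_to_genetic(1_000_000, 1e-8))
        assert c == pytest.approx(0.00995)
        t, ne = ne_at_bin(0.1, c)
        assert ne == pytest.approx((1 / (4 * 0.00995)) * 9, rel=1e-12)
        assert t == pytest.approx(1 / (2 * 0.00995), rel=1e-12)

    def test_saturated_and_overcorrected_are_undefined(self):
        with pytest.raises(UndefinedResult, match="saturated"):
            ne_at_bin(1.0, 0.01)
        with pytest.raises(UndefinedResult, match="over-corrected"):
            ne_at_bin(-0.01, 0.01)

    def test_monotone_decreasing_in_r2adj_and_c(self):
        nes = [ne_at_bin(r, 0.01)[1] for r in np.linspace(0.05, 0.9, 30)]
        assert all(a > b for a, b in zip(nes, nes[1:]))
        nes_c = [ne_at_bin(0.2, c)[1] for c in np.linspace(0.001, 0.4, 30)]
        assert all(a > b for a, b in zip(nes_c, nes_c[1:]))


class TestSvedRoundTrip:
    def test_closed_form_recovers_n_exactly(self):
        """Feeding the drift-recombination expectation through the sampling
        correction and the bin inversion returns N to 1e-6 relative."""
        for N in (20, 50, 100, 500):
            for c in (0.001, 0.005, 0.01, 0.05, 0.1, 0.25):
                for beta, n in ((1, 50), (2, 96)):
                    r2 = expected_r2_sved(N, c, n, beta=beta)
                    _, ne = ne_at_bin(adjust_r2(r2, n, beta), c)
                    assert ne == pytest.approx(N, rel=1e-6)

    def test_expected_r2_hand_values(self):
        assert expected_r2_sved(50, 0.025, math.inf) == pytest.approx(1 / 6)
        # c at the free-recombination ceiling: ~ 1/(2N) plus the sampling term
        assert expected_r2_sved(10_000, 0.5, 100) == pytest.approx(
            1 / 20_001 + 0.01, rel=1e-9)


def sved_pairs(N, n, dists, k=1e-8, beta=1, n_per=50):
    """Pairs whose r2 sits exactly at the Sved expectation for their distance."""
    pairs = []
    for d_bp in dists:
        c = sved_feldman_c(k * d_bp)
        r2 = expected_r2_sved(N, c, n, beta=beta)
        for j in range(n_per):
            pairs.append(LDPair(chrom="1", idx_a=j, idx_b=j + 1,
                                dist_bp=int(d_bp), r2=r2, n_obs=n))
    return pairs


class TestNeTrajectory:
    def test_single_bin_equals_global_means(self):
        cfg = NeLdConfig(n_bins=1, min_dist_bp=100_000, max_dist_bp=2_000_000)
        pairs = [LDPair("1", 0, 1, 500_000, 0.30, 50),
                 LDPair("1", 1, 2, 1_500_000, 0.10, 50)]
        traj = ne_trajectory(pairs, 50, cfg)
        assert len(traj.estimates) == 1
        mean_d = (500_000 + 1_500_000) / 2
        c = sved_feldman_c(physical_to_genetic(mean_d))
        t, ne = ne_at_bin(adjust_r2(0.2, 50), c)
        assert traj.estimates[0].ne == pytest.approx(ne)
        assert traj.estimates[0].t_generations == pytest.approx(t)

    def test_sved_equilibrium_round_trip_every_bin(self):
        """Pairs pinned at the Sved expectation reproduce N in every bin."""
        N, n = 75, 60
        cfg = NeLdConfig(n_bins=8, min_dist_bp=200_000, max_dist_bp=4_200_000)
        edges = np.linspace(cfg.min_dist_bp, cfg.max_dist_bp, cfg.n_bins + 1)
        centers = (edges[:-1] + edges[1:]) / 2
        traj = ne_trajectory(sved_pairs(N, n, centers), n, cfg)
        assert len(traj.estimates) == cfg.n_bins
        for e in traj.estimates:
            assert e.ne == pytest.approx(N, rel=1e-6)

    def test_constant_r2_varies_only_through_c(self):
        """With r2 fixed and negligible sampling correction the Ne profile is
        the closed form (1/(4c))(1/r2 - 1)."""
        n = 10**9
        cfg = NeLdConfig(n_bins=5, min_dist_bp=500_000, max_dist_bp=3_000_000)
        pairs = [LDPair("1", 0, 1, int(d), 0.2, n)
                 for d in np.linspace(550_000, 2_950_000, 500)]
        traj = ne_trajectory(pairs, n, cfg)
        for e in traj.estimates:
            assert e.ne == pytest.approx((1 / (4 * e.c)) * (1 / 0.2 - 1), rel=1e-6)

    def test_sorted_by_t_and_drops_reported(self):
        cfg = NeLdConfig(n_bins=3, min_dist_bp=100_000, max_dist_bp=1_000_000)
        pairs = [LDPair("1", 0, 1, 200_000, 0.05, 10),  # below the 1/n floor
                 LDPair("1", 1, 2, 500_000, 0.30, 10),
                 LDPair("1", 2, 3, 900_000, 0.25, 10)]
        traj = ne_trajectory(pairs, 10, cfg)
        ts = [e.t_generations for e in traj.estimates]
        assert ts == sorted(ts)
        assert any("over-corrected" in d["reason"] for d in traj.dropped)

    def test_shrinking_max_dist_probes_older_generations(self):
        n = 50
        wide = NeLdConfig(n_bins=5, min_dist_bp=100_000, max_dist_bp=5_000_000)
        narrow = NeLdConfig(n_bins=5, min_dist_bp=100_000, max_dist_bp=1_000_000)
        dists = np.linspace(150_000, 4_900_000, 300)
        pairs = sved_pairs(60, n, dists, n_per=2)
        t_wide = min(e.t_generations for e in ne_trajectory(pairs, n, wide).estimates)
        t_narrow = min(e.t_generations
                       for e in ne_trajectory(pairs, n, narrow).estimates)
        assert t_narrow > t_wide

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            NeLdConfig(beta=3)
        with pytest.raises(ConfigError):
            NeLdConfig(min_dist_bp=10, max_dist_bp=10)
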