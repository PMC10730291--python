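"""Dip statistic/test, critical bandwidth, mode location, cumulative."""

import numpy as np
import pytest

import floracue as fc
from floracue.modality import count_modes, kde_density

from _oracles import dip_brute_force


class TestDipStatistic:
    def test_matches_lp_oracle_small_samples(self, rng):
        """Exact agreement with a brute-force minimax search for n<=12."""
        for trial in range(60):
            n = int(rng.integers(4, 13))
            if trial % 3 == 0:
                x = rng.normal(500, 30, n)
            elif trial % 3 == 1:
                x = np.concatenate([rng.normal(400, 5, n // 2),
                                    rng.normal(600, 5, n - n // 2)])
            else:
                x = rng.uniform(300, 700, n)
            assert fc.dip_statistic(x) == pytest.approx(
                dip_brute_force(x), abs=1e-9)

    def test_two_point_masses_approach_supremum(self, rng):
        x = np.concatenate([np.full(200, 400.0), np.full(200, 600.0)])
        x = x + rng.normal(0, 1e-9, x.size)
        assert fc.dip_statistic(x) == pytest.approx(0.25, abs=1e-3)

    def test_narrow_gaussian_small_dip(self, rng):
        x = rng.normal(500, 4, 3000)
        assert fc.dip_statistic(x) < 0.02

    def test_affine_invariance(self, rng):
        x = rng.normal(0, 1, 80)
        d = fc.dip_statistic(x)
        assert fc.dip_statistic(3.5 * x - 41.0) == pytest.approx(d, abs=1e-12)
        assert fc.dip_statistic(-2.0 * x + 7.0) == pytest.approx(d, abs=1e-12)

    def test_requires_four_points(self):
        with pytest.raises(ValueError, match="n >= 4"):
            fc.dip_statistic([1.0, 2.0, 3.0])

    def test_floor_is_half_inverse_n(self, rng):
        for n in (4, 9, 25):
            x = rng.uniform(0, 1, n)
            assert fc.dip_statistic(x) >= 1.0 / (2 * n) - 1e-12


class TestDipTest:
    def test_unimodal_sample_not_rejected(self, rng):
        x = rng.normal(500, 15, 150)
        res = fc.dip_test(x, n_bootstrap=500, seed=1)
        assert res.p_value > 0.05

    def test_bimodal_sample_rejected(self, rng):
        x = np.concatenate([rng.normal(410, 8, 100), rng.normal(590, 8, 100)])
        res = fc.dip_test(x, n_bootstrap=500, seed=1)
        assert res.p_value < 0.01

    def test_monte_carlo_consistency(self, rng):
        x = np.concatenate([rng.normal(440, 20, 60), rng.normal(560, 20, 60)])
        p1 = fc.dip_test(x, n_bootstrap=500, seed=3).p_value
        p2 = fc.dip_test(x, n_bootstrap=1000, seed=4).p_value
        se = np.sqrt(max(p1, 1 / 500) * (1 - min(p1, 1 - 1 / 500)) / 500)
        assert abs(p1 - p2) <= max(4 * se, 0.02)

    def test_reproducible_from_seed(self, rng):
        x = rng.normal(500, 20, 60)
        r1 = fc.dip_test(x, n_bootstrap=200, seed=7)
        r2 = fc.dip_test(x, n_bootstrap=200, seed=7)
        assert r1 == r2


class TestCriticalBandwidth:
    def test_monotone_in_k(self, rng):
        x = np.concatenate([rng.normal(400, 3, 150), rng.normal(600, 3, 150)])
        h1 = fc.critical_bandwidth(x, 1)
        h2 = fc.critical_bandwidth(x, 2)
        assert h2 < h1
        assert h1 > 30  # must smooth across the 200 nm separation

    def test_bracket_property(self, rng):
        """At h_crit the KDE has <= k modes; 1% below it has more."""
        for _ in range(10):
            x = np.concatenate([
                rng.normal(rng.uniform(350, 450), rng.uniform(5, 15), 80),
                rng.normal(rng.uniform(500, 650), rng.uniform(5, 15), 80)])
            for k in (1, 2):
                h = fc.critical_bandwidth(x, k)
                assert count_modes(x, h) <= k
                assert count_modes(x, 0.99 * h) > k

    def test_single_gaussian_unimodal_at_crit(self, rng):
        x = rng.normal(500, 10, 200)
        h = fc.critical_bandwidth(x, 1)
        assert count_modes(x, h) == 1

    def test_mode_count_monotone_in_bandwidth(self, rng):
        x = np.concatenate([rng.normal(380, 6, 70), rng.normal(480, 6, 70),
                            rng.normal(620, 6, 70)])
        hs = np.linspace(1.0, 80.0, 40)
        counts = [count_modes(x, h) for h in hs]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_weighted_equals_expanded(self, rng):
        centres = np.array([400.0, 405.0, 500.0, 505.0, 510.0])
        weights = np.array([3, 1, 2, 5, 1])
        expanded = np.repeat(centres, weights)
        for k in (1, 2):
            hw = fc.critical_bandwidth(centres, k, weights=weights)
            he = fc.critical_bandwidth(expanded, k)
            assert hw == pytest.approx(he, rel=0.02)


class TestLocateModes:
    def test_single_gaussian_mode_recovered(self, rng):
        x = rng.normal(500, 12, 300)
        rep = fc.locate_modes(x, 1)
        assert rep.mode_positions[0] == pytest.approx(500, abs=5)

    def test_planted_mixture_recovered(self, rng):
        x = np.concatenate([rng.normal(410, 12, 200),
                            rng.normal(530, 12, 200)])
        rep = fc.locate_modes(x, 2)
        assert rep.mode_positions[0] == pytest.approx(410, abs=5)
        assert rep.mode_positions[1] == pytest.approx(530, abs=5)

    def test_positions_sorted_in_range(self, rng):
        x = rng.uniform(350, 650, 200)
        rep = fc.locate_modes(x, 3)
        pos = np.array(rep.mode_positions)
        assert np.all(np.diff(pos) > 0)
        assert pos.min() >= 300 and pos.max() <= 700


class TestSelectModeCount:
    def test_unimodal_returns_one(self, rng):
        x = rng.normal(500, 15, 300)
        assert fc.select_mode_count(x, max_k=4, n_bootstrap=200, seed=5) == 1

    def test_clear_two_mixture_returns_two(self, rng):
        x = np.concatenate([rng.normal(400, 8, 200),
                            rng.normal(600, 8, 200)])
        assert fc.select_mode_count(x, max_k=4, n_bootstrap=200, seed=5) == 2

    def test_max_k_one_always_one(self, rng):
        x = np.concatenate([rng.normal(400, 5, 50), rng.normal(600, 5, 50)])
        assert fc.select_mode_count(x, max_k=1, n_bootstrap=100, seed=5) == 1


class TestCumulativeLeftFraction:
    def test_all_left(self):
        assert fc.cumulative_left_fraction(np.full(10, 400.0), 500.0) == 1.0

    def test_half_left(self):
        assert fc.cumulative_left_fraction([450.0, 550.0], 500.0) == 0.5

    def test_strict_inequality_at_reference(self):
        assert fc.cumulative_left_fraction([500.0, 400.0], 500.0) == 0.5

    def test_monotone_in_reference(self, rng):
        x = rng.uniform(300, 700, 300)
        refs = np.linspace(300, 700, 21)
        fr = [fc.cumulative_left_fraction(x, r) for r in refs]
        assert all(a <= b for a, b in zip(fr, fr[1:]))

    def test_weighted_binned_counts_fully_below_edge(self):
        centres = np.array([497.5, 502.5])
        counts = np.array([30.0, 10.0])
        frac = fc.cumulative_left_fraction(centres, 500.0, weights=counts)
        assert frac == 0.75

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            fc.cumulative_left_fraction([], 500.0)


class TestKdeDensity:
    def test_single_point_symmetric_unit_mass(self):
        grid, dens = fc.kde_density([500.0], 10.0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-6)
        i = np.searchsorted(grid, 500.0)
        assert np.allclose(dens[i - 50:i], dens[i + 50:i:-1], rtol=1e-6)

    def test_two_points_linear_superposition(self):
        g, d2 = fc.kde_density([420.0, 580.0], 15.0)
        _, da = fc.kde_density([420.0], 15.0)
        _, db = fc.kde_density([580.0], 15.0)
        # same renormalisation domain, so the mixture is the average
        assert np.allclose(d2, 0.5 * (da + db), rtol=1e-6, atol=1e-9)

    def test_binned_approximates_raw(self, rng):
        x = rng.uniform(320, 680, 2000)
        binned = fc.bin_markers(x)
        g, d_raw = fc.kde_density(x, 15.0)
        _, d_bin = fc.kde_density(binned.bin_centres, 15.0,
                                  weights=binned.counts)
        # binning moves each point by < 2.5 nm, so the density changes by
        # at most shift * max|kernel slope| per unit mass (10% slack for
        # the window renormalisation)
        h = 15.0
        bound = 1.1 * 2.5 * np.exp(-0.5) / (h * h * np.sqrt(2 * np.pi))
        assert np.max(np.abs(d_raw - d_bin)) < bound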