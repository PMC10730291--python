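"""Marker detection: smoothing, extrema, window search, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import floracue as fc
from floracue.markers import _extrema_indices

from _oracles import local_extrema_exhaustive, markers_brute_force
from conftest import make_spectrum, ramp_spectrum, random_piecewise_linear


class TestSmoothing:
    def test_constant_unchanged(self, grid):
        s = make_spectrum(np.full(grid.size, 50.0))
        out = fc.smooth_spectrum(s, 21)
        assert np.allclose(out.reflectance, 50.0)

    def test_window_one_is_identity(self, rng, grid):
        s = make_spectrum(rng.uniform(0, 80, grid.size))
        assert np.array_equal(fc.smooth_spectrum(s, 1).reflectance,
                              s.reflectance)

    def test_spike_spread_by_window(self, grid):
        y = np.full(grid.size, 20.0)
        y[200] += 10.0  # 500 nm
        out = fc.smooth_spectrum(make_spectrum(y), 21)
        assert out.reflectance[200] == pytest.approx(20.0 + 10.0 / 21)

    def test_matches_direct_moving_average(self, rng, grid):
        y = rng.uniform(0, 60, grid.size)
        out = fc.smooth_spectrum(make_spectrum(y), 11).reflectance
        # direct oracle with symmetric boundary truncation
        for i in (0, 3, 5, 200, 397, 400):
            k = min(5, i, grid.size - 1 - i)
            assert out[i] == pytest.approx(y[i - k:i + k + 1].mean())

    def test_even_window_rejected(self, grid):
        with pytest.raises(ValueError, match="odd"):
            fc.smooth_spectrum(make_spectrum(np.zeros(grid.size)), 10)


class TestExtrema:
    def test_monotone_has_no_interior_extrema(self, grid):
        s = make_spectrum(np.linspace(5, 60, grid.size))
        assert fc.detect_extrema(s, lookahead=5, min_delta=1.0) == []

    def test_constant_has_no_extrema(self, grid):
        s = make_spectrum(np.full(grid.size, 30.0))
        assert fc.detect_extrema(s, lookahead=5, min_delta=1.0) == []

    def test_two_gaussian_bumps_match_exhaustive_scan(self, grid):
        y = 10 + 30 * np.exp(-0.5 * ((grid - 420) / 25) ** 2) \
            + 25 * np.exp(-0.5 * ((grid - 580) / 25) ** 2)
        found = _extrema_indices(y, lookahead=5, min_delta=1.0)
        oracle = local_extrema_exhaustive(y, lookahead=5)
        assert [(i, k) for i, k in found] == oracle
        kinds = [k for _, k in found]
        assert kinds == ["max", "min", "max"]

    def test_alternation(self, rng, grid):
        for _ in range(20):
            s = random_piecewise_linear(rng)
            y = fc.smooth_spectrum(s, 21).reflectance
            kinds = [k for _, k in _extrema_indices(y, 5, 1.25)]
            assert all(a != b for a, b in zip(kinds, kinds[1:]))

    def test_sub_delta_wiggle_not_confirmed(self, grid):
        y = 20 + 0.5 * np.sin((grid - 300) / 15.0)  # amplitude < min_delta
        assert _extrema_indices(y, 5, 1.25) == []


class TestExtractMarkers:
    def test_flat_spectrum_empty(self, grid):
        s = make_spectrum(np.full(grid.size, 42.0))
        assert fc.extract_markers(s, fc.DetectionConfig(threshold=5)) == []

    def test_symmetric_ramp_marker(self):
        # 10% -> 40% linear ramp over 495-505 nm: midpoint forced at 500,
        # magnitude is the full 30-point jump, span the 10 nm ramp width
        s = ramp_spectrum()
        cfg = fc.DetectionConfig(threshold=20, smoothing_window=1)
        (m,) = fc.extract_markers(s, cfg)
        assert m.wavelength == pytest.approx(500.0)
        assert m.magnitude == pytest.approx(30.0)
        assert m.span == pytest.approx(10.0)
        assert m.direction == "rise"

    def test_smoothing_preserves_symmetric_midpoint(self):
        (m,) = fc.extract_markers(ramp_spectrum(), fc.DetectionConfig(
            threshold=20))
        assert m.wavelength == pytest.approx(500.0, abs=0.01)
        assert m.magnitude == pytest.approx(30.0, abs=0.5)

    def test_gradual_change_over_50nm_not_marked(self, grid):
        # 30-point rise spread over 200 nm: no sub-window of < 50 nm
        # reaches the 20-point threshold
        y = np.interp(grid, [300, 400, 600, 700], [10, 10, 40, 40])
        assert fc.extract_markers(make_spectrum(y),
                                  fc.DetectionConfig(threshold=20)) == []

    def test_strict_span_limit(self, grid):
        # a 20-point rise spread over exactly 50 nm (0.4 points/nm): every
        # window narrower than 50 nm changes by < 20, and the 50 nm window
        # itself is excluded by the strict "< 50 nm" rule -> no marker
        y = np.interp(grid, [300, 450, 500, 700], [10, 10, 30, 30])
        cfg = fc.DetectionConfig(threshold=20, smoothing_window=1)
        assert fc.extract_markers(make_spectrum(y), cfg) == []

    def test_direction_filter(self):
        rise_only = fc.DetectionConfig(threshold=20, smoothing_window=1,
                                       directions=("rise",))
        fall = ramp_spectrum(lo=40.0, hi=10.0)  # downward step
        assert fc.extract_markers(fall, rise_only) == []
        both = fc.DetectionConfig(threshold=20, smoothing_window=1)
        (m,) = fc.extract_markers(fall, both)
        assert m.direction == "fall"

    def test_mirror_symmetry_swaps_direction_keeps_position(self, rng):
        for _ in range(25):
            s = random_piecewise_linear(rng)
            cfg = fc.DetectionConfig(threshold=12)
            up = fc.extract_markers(s, cfg)
            mirrored = make_spectrum(80.0 - s.reflectance)
            down = fc.extract_markers(mirrored, cfg)
            assert len(up) == len(down)
            for a, b in zip(up, down):
                assert a.wavelength == pytest.approx(b.wavelength, abs=1e-9)
                assert a.direction != b.direction
                assert a.magnitude == pytest.approx(b.magnitude)

    def test_marker_invariants_on_random_spectra(self, rng):
        cfg = fc.DetectionConfig(threshold=10)
        for _ in range(50):
            s = random_piecewise_linear(rng)
            for m in fc.extract_markers(s, cfg):
                assert m.magnitude >= cfg.threshold
                assert 300.0 <= m.wavelength <= 700.0

    def test_threshold_monotonicity(self, rng):
        # with the segmentation held fixed (shared min_delta), markers at
        # a higher threshold come only from segments that already marked
        # at the lower threshold
        from floracue.markers import _extrema_indices, _segment_bounds

        def segment_of(pos, segments, wave):
            for a, b in segments:
                if wave[a] <= pos <= wave[b]:
                    return (a, b)
            raise AssertionError(f"marker at {pos} outside all segments")

        for _ in range(30):
            s = random_piecewise_linear(rng)
            lo_cfg = fc.DetectionConfig(threshold=8, min_delta=2.0)
            hi_cfg = fc.DetectionConfig(threshold=16, min_delta=2.0)
            low = fc.extract_markers(s, lo_cfg)
            high = fc.extract_markers(s, hi_cfg)
            assert len(high) <= len(low)
            sm = fc.smooth_spectrum(s, 21)
            segs = _segment_bounds(
                sm.reflectance.size,
                _extrema_indices(sm.reflectance, 5, 2.0))
            low_segs = {segment_of(m.wavelength, segs, sm.wavelengths)
                        for m in low}
            for m in high:
                assert segment_of(m.wavelength, segs,
                                  sm.wavelengths) in low_segs

    def test_matches_pair_scan_oracle(self, rng):
        cfg = fc.DetectionConfig(threshold=10)
        total = 0
        for _ in range(120):
            s = random_piecewise_linear(rng)
            mine = fc.extract_markers(s, cfg)
            oracle = markers_brute_force(s, cfg)
            assert len(mine) == len(oracle)
            for m, (pos, direction, mag, span) in zip(mine, oracle):
                assert m.wavelength == pytest.approx(pos, abs=0.5)
                assert m.direction == direction
                assert m.magnitude == pytest.approx(mag)
                assert m.span == pytest.approx(span)
            total += len(mine)
        assert total > 100  # the comparison actually exercised markers


class TestPoolDetection:
    def test_flat_pool_empty_table(self, grid):
        pool = fc.SamplePool([
            fc.Spectrum(f"f{i}", "other", grid, np.full(grid.size, 25.0))
            for i in range(3)])
        table = fc.markers_for_pool(pool, fc.DetectionConfig(threshold=5))
        assert len(table) == 0

    def test_identical_samples_identical_markers(self, grid):
        pool = fc.SamplePool([
            ramp_spectrum(sample_id=f"r{i}") for i in range(4)])
        table = fc.markers_for_pool(
            pool, fc.DetectionConfig(threshold=20, smoothing_window=1))
        assert len(table) == 4
        assert table["marker_nm"].nunique() == 1

    def test_additivity_over_samples(self, rng):
        cfg = fc.DetectionConfig(threshold=10)
        specs = [random_piecewise_linear(rng) for _ in range(10)]
        for i, s in enumerate(specs):
            object.__setattr__(s, "sample_id", f"s{i}")
        pool = fc.SamplePool(specs)
        table = fc.markers_for_pool(pool, cfg)
        per_sample = sum(len(fc.extract_markers(s, cfg)) for s in specs)
        assert len(table) == per_sample


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_every_marker_satisfies_contract(seed):
    """Magnitude >= threshold, 300 <= position <= 700, for any spectrum."""
    rng = np.random.default_rng(seed)
    s = random_piecewise_linear(rng)
    cfg = fc.DetectionConfig(threshold=7.5)
    for m in fc.extract_markers(s, cfg):
        assert m.magnitude >= 7.5
        assert 300.0 <= m.wavelength <= 700.0
        assert m.direction in ("rise", "fall")
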