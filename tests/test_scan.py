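"""Window construction, sliding-window fitting, threshold constructions."""

import numpy as np
import pytest

from bsascan import (ed_threshold_median_sd, ed_threshold_quantile, fit_track,
                     make_windows, null_envelope_delta)


def brute_force_window_means(positions, values, starts, ends):
    """Independent oracle: direct per-window scan over all sites."""
    out = []
    for s, e in zip(starts, ends):
        inside = [v for p, v in zip(positions, values) if s <= p <= e]
        out.append(np.mean(inside) if inside else np.nan)
    return np.array(out)


class TestMakeWindows:
    def test_two_megabase_chromosome_enumeration(self):
        starts, ends = make_windows(2_000_000, 1_000_000, 10_000)
        assert len(starts) == 200
        assert (starts[0], ends[0]) == (1, 1_000_000)
        full = np.sum(ends - starts + 1 == 1_000_000)
        assert full == 101

    def test_chromosome_equal_to_window(self):
        starts, ends = make_windows(1_000_000, 1_000_000, 250_000)
        assert list(starts) == [1, 250_001, 500_001, 750_001]
        assert ends[0] == 1_000_000
        assert all(e == 1_000_000 for e in ends)

    def test_step_equal_to_window_tiles_without_overlap(self):
        starts, ends = make_windows(1_000_000, 100_000, 100_000)
        assert all(starts[i + 1] == ends[i] + 1 for i in range(len(starts) - 1))

    @pytest.mark.parametrize("window, step", [(0, 10), (100, 0), (50, 100)])
    def test_invalid_sizes_rejected(self, window, step):
        with pytest.raises(ValueError):
            make_windows(1000, window, step)


class TestFitTrack:
    def test_mean_fit_of_known_values(self):
        windows = make_windows(1000, 1000, 1000)
        track = fit_track([100, 500, 900], [0.2, 0.4, 0.6], "chr1", windows,
                          "delta_snp_index", fit_method="mean")
        assert track.fitted[0] == pytest.approx(0.4)
        assert track.n_sites[0] == 3

    def test_distance_weighted_single_site_is_identity(self):
        windows = make_windows(1000, 1000, 1000)
        for pos in (1, 137, 500, 999):
            track = fit_track([pos], [0.7], "chr1", windows, "delta_snp_index",
                              fit_method="distance_weighted")
            assert track.fitted[0] == pytest.approx(0.7)

    def test_mean_fit_matches_brute_force_exactly(self, rng):
        positions = np.sort(rng.integers(1, 500_000, size=50))
        values = rng.normal(size=50)
        windows = make_windows(500_000, 100_000, 20_000)
        track = fit_track(positions, values, "chr1", windows,
                          "delta_snp_index", fit_method="mean")
        oracle = brute_force_window_means(positions, values, *windows)
        np.testing.assert_array_equal(np.isnan(track.fitted), np.isnan(oracle))
        ok = ~np.isnan(oracle)
        np.testing.assert_array_equal(track.fitted[ok], oracle[ok])

    def test_unsorted_positions_rejected(self):
        windows = make_windows(1000, 1000, 1000)
        with pytest.raises(ValueError, match="sorted"):
            fit_track([500, 100], [0.1, 0.2], "chr1", windows,
                      "delta_snp_index")

    def test_empty_windows_marked_missing(self):
        windows = make_windows(10_000, 1_000, 1_000)
        track = fit_track([1500], [0.3], "chr1", windows, "delta_snp_index")
        assert np.isnan(track.fitted[5])
        assert track.n_sites[5] == 0
        assert track.fitted[1] == pytest.approx(0.3)


class TestNullEnvelope:
    def test_null_delta_is_symmetric_about_zero(self, rng):
        # the median of |delta| matches the 50% envelope by definition;
        # signed delta has median ~0 by bulk symmetry
        ts = null_envelope_delta(70, 70, 50, levels=(0.5,), reps=50_000, rng=rng)
        two_n = 100
        r2 = np.random.default_rng(99)
        d = (r2.binomial(70, r2.binomial(two_n, 0.5, 50_000) / two_n) / 70
             - r2.binomial(70, r2.binomial(two_n, 0.5, 50_000) / two_n) / 70)
        assert np.median(d) == pytest.approx(0.0, abs=0.01)
        assert ts.at(0.5) == pytest.approx(np.median(np.abs(d)), abs=0.01)

    def test_envelope_vanishes_in_consistency_limit(self, rng):
        ts = null_envelope_delta(10_000, 10_000, 10_000, levels=(0.99,),
                                 reps=5_000, rng=rng)
        assert ts.at(0.99) < 0.05

    def test_levels_are_ordered_and_reproducible(self, rng):
        ts = null_envelope_delta(70, 70, 50, reps=100_000, rng=rng)
        t90, t95, t99 = ts.at(0.90), ts.at(0.95), ts.at(0.99)
        assert t90 < t95 < t99
        oracle = null_envelope_delta(70, 70, 50, reps=100_000,
                                     rng=np.random.default_rng(777))
        for lvl in (0.90, 0.95, 0.99):
            assert ts.at(lvl) == pytest.approx(oracle.at(lvl), abs=0.01)

    def test_threshold_monotone_in_depth_and_bulk_size(self):
        grid = {}
        for depth in (20, 70, 200):
            for bulk in (20, 50, 200):
                ts = null_envelope_delta(depth, depth, bulk, levels=(0.99,),
                                         reps=100_000,
                                         rng=np.random.default_rng(5))
                grid[depth, bulk] = ts.at(0.99)
        for bulk in (20, 50, 200):
            assert grid[20, bulk] >= grid[70, bulk] >= grid[200, bulk]
        for depth in (20, 70, 200):
            assert grid[depth, 20] >= grid[depth, 50] >= grid[depth, 200]

    def test_small_rep_count_rejected(self, rng):
        with pytest.raises(ValueError, match="reps"):
            null_envelope_delta(70, 70, 50, reps=100, rng=rng)


class TestEdThresholds:
    def test_constant_track_threshold_is_the_constant(self):
        assert ed_threshold_median_sd([1, 1, 1, 1]).scalar == pytest.approx(1.0)

    def test_median_plus_three_sample_sds(self):
        # median 1, sample SD sqrt(2): threshold 1 + 3*sqrt(2)
        assert ed_threshold_median_sd([0, 2]).scalar == pytest.approx(1 + 3 * np.sqrt(2))

    def test_missing_windows_excluded(self):
        t = ed_threshold_median_sd([np.nan, 0, 2, np.nan]).scalar
        assert t == pytest.approx(1 + 3 * np.sqrt(2))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            ed_threshold_median_sd([np.nan, np.nan])

    def test_quantile_linear_interpolation(self):
        values = np.arange(1.0, 101.0)
        assert ed_threshold_quantile(values, 0.99).scalar == pytest.approx(99.01)

    def test_quantile_of_constant_track(self):
        assert ed_threshold_quantile([0.4, 0.4, 0.4]).scalar == pytest.approx(0.4)

    def test_quantile_boundary_contract(self):
        with pytest.raises(ValueError, match="q must"):
            ed_threshold_quantile([1.0, 2.0], 1.0)
        assert ed_threshold_quantile(np.arange(100.0), 0.999999).scalar == \
            pytest.approx(99.0, abs=1e-3)
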