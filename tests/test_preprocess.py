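"""Zone split, combination averaging, truncation, smoothing and SNV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import peachspec as ps
from peachspec.errors import (
    DegenerateSampleError,
    DegenerateSpectrumError,
    InvalidParameterError,
)


class TestSplitScanCounts:
    @pytest.mark.parametrize(
        "n_raw, expected",
        [(10, (4, 2, 4)), (9, (3, 3, 3)), (31, (11, 9, 11)), (5, (2, 1, 2)), (20, (7, 6, 7))],
    )
    def test_outer_zones_take_ceil_third(self, n_raw, expected):
        s = ps.split_scan_counts(n_raw)
        assert (s.n_s1, s.n_s2, s.n_s3) == expected

    @pytest.mark.parametrize("n_raw", [0, 1, 4])
    def test_too_few_scans_rejected(self, n_raw):
        with pytest.raises(DegenerateSampleError):
            ps.split_scan_counts(n_raw)

    @given(st.integers(min_value=5, max_value=10_000))
    def test_counts_partition_and_outer_symmetry(self, n_raw):
        s = ps.split_scan_counts(n_raw)
        assert s.n_s1 == s.n_s3
        assert s.n_s1 + s.n_s2 + s.n_s3 == n_raw
        assert s.n_s2 >= 1

    def test_zone_indices_are_contiguous_in_scan_order(self):
        s = ps.split_scan_counts(10)
        assert list(s.indices(ps.Zone.S1)) == [0, 1, 2, 3]
        assert list(s.indices(ps.Zone.S2)) == [4, 5]
        assert list(s.indices(ps.Zone.S3)) == [6, 7, 8, 9]


def _scan_set(scans, grid=None):
    scans = np.asarray(scans, dtype=float)
    grid = grid or ps.WavelengthGrid(560.0, 560.0 + (scans.shape[1] - 1) * 0.25, 0.25)
    return ps.FruitScanSet(
        sample_id="X",
        orientation="O1",
        ssc_true=10.0,
        diameter_mm=50.0,
        grid=grid,
        scans=scans,
    )


class TestCombinationMean:
    def test_identical_scans_any_combination(self, rng):
        scan = rng.random(16)
        fs = _scan_set(np.tile(scan, (7, 1)))
        for comb in ps.Combination:
            np.testing.assert_allclose(ps.combination_mean(fs, comb), scan)

    def test_ten_scans_s1s3_mean_of_eight_outer(self, rng):
        scans = rng.random((10, 12))
        fs = _scan_set(scans)
        outer = np.vstack([scans[:4], scans[6:]])
        np.testing.assert_allclose(
            ps.combination_mean(fs, ps.Combination.S1S3), outer.mean(axis=0)
        )
        np.testing.assert_allclose(
            ps.combination_mean(fs, ps.Combination.S2), scans[4:6].mean(axis=0)
        )

    def test_s1s2s3_equals_plain_mean_of_all_scans(self, rng):
        scans = rng.random((13, 20))
        fs = _scan_set(scans)
        np.testing.assert_allclose(
            ps.combination_mean(fs, ps.Combination.S1S2S3), scans.mean(axis=0)
        )

    def test_scan_count_weighted_conservation(self, rng):
        # mean(all) must equal the scan-count weighted mean of S1S3 and S2
        scans = rng.random((11, 8))
        fs = _scan_set(scans)
        split = ps.split_scan_counts(11)
        n_outer = split.n_s1 + split.n_s3
        combined = (
            n_outer * ps.combination_mean(fs, ps.Combination.S1S3)
            + split.n_s2 * ps.combination_mean(fs, ps.Combination.S2)
        ) / 11
        np.testing.assert_allclose(
            combined, ps.combination_mean(fs, ps.Combination.S1S2S3), atol=1e-12
        )


class TestTruncate:
    def test_default_bounds_give_1497_points(self):
        spec = np.arange(ps.FULL_GRID.n_points, dtype=float)
        out, grid = ps.truncate(spec, ps.FULL_GRID)
        assert out.shape == (1497,)
        assert grid.n_points == 1497
        assert grid.start_nm == pytest.approx(652.25)
        assert grid.stop_nm == pytest.approx(1026.25)

    def test_full_bounds_are_identity(self):
        g = ps.WavelengthGrid(560.0, 570.0, 0.5)
        spec = np.arange(g.n_points, dtype=float)
        out, grid2 = ps.truncate(spec, g, 560.0, 570.0)
        np.testing.assert_array_equal(out, spec)
        assert grid2 == g

    def test_on_grid_bound_accepted_off_grid_rejected(self):
        g = ps.WavelengthGrid(652.25, 660.25, 0.25)
        spec = np.zeros(g.n_points)
        ps.truncate(spec, g, 653.0, 660.0)  # 653.0 lies on a 0.25 grid
        with pytest.raises(InvalidParameterError):
            ps.truncate(spec, g, 653.1, 660.0)


class TestMovingAverage:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(ps.moving_average(np.full(30, 3.5), 9), 3.5)

    def test_linear_ramp_unchanged_everywhere(self):
        # symmetric (possibly shrunken) windows preserve linear trends
        x = 2.0 * np.arange(40) - 7.0
        np.testing.assert_allclose(ps.moving_average(x, 9), x, atol=1e-12)

    def test_single_spike_window9(self):
        x = np.array([0, 0, 0, 0, 9, 0, 0, 0, 0], dtype=float)
        out = ps.moving_average(x, 9)
        assert out[4] == pytest.approx(1.0)
        # edge windows shrink to a single point
        assert out[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("window", [0, 2, 8, -3])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(InvalidParameterError):
            ps.moving_average(np.zeros(20), window)

    def test_window_longer_than_spectrum_rejected(self):
        with pytest.raises(InvalidParameterError):
            ps.moving_average(np.zeros(5), 9)

    @given(st.lists(st.floats(-1e3, 1e3), min_size=9, max_size=60))
    @settings(max_examples=50)
    def test_never_widens_range(self, values):
        x = np.array(values)
        out = ps.moving_average(x, 9)
        assert out.max() <= x.max() + 1e-9
        assert out.min() >= x.min() - 1e-9


class TestSNV:
    def test_small_example(self):
        np.testing.assert_allclose(ps.snv(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_output_standardised(self, rng):
        out = ps.snv(rng.random(200))
        assert abs(out.mean()) < 1e-10
        assert abs(out.std(ddof=1) - 1) < 1e-10

    @given(
        st.floats(0.1, 50.0),
        st.floats(-100.0, 100.0),
    )
    @settings(max_examples=50)
    def test_affine_invariance(self, a, b):
        x = np.sin(np.linspace(0, 7, 64)) * 3 + 1
        np.testing.assert_allclose(ps.snv(a * x + b), ps.snv(x), atol=1e-8)

    def test_constant_spectrum_rejected_not_nan(self):
        with pytest.raises(DegenerateSpectrumError):
            ps.snv(np.full(10, 2.0))

    def test_population_divisor_flag(self):
        x = np.array([1.0, 2.0, 3.0])
        out = ps.snv(x, ddof=0)
        assert abs(out.std(ddof=0) - 1) < 1e-12


class TestPipeline:
    def test_rows_are_snv_normalised_on_1497_points(self, default_o1_dataset):
        mat = ps.preprocess_pipeline(default_o1_dataset[:10], ps.Combination.S1S3)
        assert mat.values.shape[1] == 1497
        np.testing.assert_allclose(mat.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(mat.values.std(axis=1, ddof=1), 1, atol=1e-10)

    def test_s1s2s3_matches_plain_mean_route(self, small_dataset, small_config):
        # the whole-fruit route is by definition the all-scan mean spectrum
        fs = small_dataset[0]
        mean_all = fs.scans.mean(axis=0)
        trunc, _ = ps.truncate(mean_all, fs.grid, small_config.lo_nm, small_config.hi_nm)
        expected = ps.snv(ps.moving_average(trunc, 9))
        mat = ps.preprocess_pipeline(
            [fs], ps.Combination.S1S2S3, lo_nm=small_config.lo_nm, hi_nm=small_config.hi_nm
        )
        np.testing.assert_allclose(mat.values[0], expected, atol=1e-12)

    def test_snv_cancels_scatter_and_offset(self):
        # two noise-free fruits with equal SSC, differing only by per-scan
        # multiplicative scatter, give identical pipeline rows
        base = ps.SynthConfig(noise_sd=0.0, scatter_sigma=0.0, seed=5)
        rng1 = np.random.default_rng(1)
        fs_clean = ps.generate_fruit(base, "A", "O1", rng1, ssc_true=11.0, diameter_mm=60.0)
        scatter = np.random.default_rng(2).lognormal(0, 0.3, size=fs_clean.n_scans)
        fs_scattered = ps.FruitScanSet(
            "B", "O1", 11.0, 60.0, base.grid, fs_clean.scans * scatter[:, None]
        )
        m1 = ps.preprocess_pipeline([fs_clean], ps.Combination.S1S3)
        m2 = ps.preprocess_pipeline([fs_scattered], ps.Combination.S1S3)
        # scatter varies per scan, so averaging mixes factors; per-fruit
        # common factors cancel exactly, per-scan ones nearly so
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-6)

    def test_pure_per_spectrum_affine_effects_cancel_exactly(self):
        base = ps.SynthConfig(noise_sd=0.0, scatter_sigma=0.0, seed=5)
        rng = np.random.default_rng(3)
        fs = ps.generate_fruit(base, "A", "O1", rng, ssc_true=9.0, diameter_mm=60.0)
        fs_affine = ps.FruitScanSet(
            "B", "O1", 9.0, 60.0, base.grid, fs.scans * 1.7 + 0.02
        )
        m1 = ps.preprocess_pipeline([fs], ps.Combination.S1S2S3)
        m2 = ps.preprocess_pipeline([fs_affine], ps.Combination.S1S2S3)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-10)

    def test_permutation_equivariance(self, small_dataset):
        subset = [f for f in small_dataset if f.orientation is ps.Orientation.O1][:8]
        m1 = ps.preprocess_pipeline(subset, ps.Combination.S1S3, lo_nm=650.0, hi_nm=1030.0)
        m2 = ps.preprocess_pipeline(subset[::-1], ps.Combination.S1S3, lo_nm=650.0, hi_nm=1030.0)
        np.testing.assert_allclose(m1.values, m2.values[::-1], atol=0)
        assert m1.sample_ids == m2.sample_ids[::-1]

    def test_error_annotated_with_sample_id(self):
        g = ps.WavelengthGrid(560.0, 565.0, 1.0)
        fs = ps.FruitScanSet("BAD01", "O1", 10.0, 50.0, g, np.zeros((6, 6)))
        with pytest.raises(DegenerateSpectrumError, match="BAD01"):
            ps.preprocess_pipeline([fs], ps.Combination.S1S3, window=3, lo_nm=560.0, hi_nm=565.0)
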