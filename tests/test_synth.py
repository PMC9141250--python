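"""Synthetic-spectra generator: geometry, determinism, signal structure."""

import numpy as np
import pytest

import peachspec as ps
from peachspec.errors import InvalidParameterError
from peachspec.synth import FruitEffects, scan_absorbance, truncated_ssc_mean


class TestScanGeometry:
    @pytest.mark.parametrize(
        "diameter, expected", [(75, 31), (2.4, 1), (48, 20), (76.8, 32)]
    )
    def test_scan_count_from_diameter(self, diameter, expected):
        assert ps.n_scans_for_diameter(diameter, 480, 0.005) == expected

    @pytest.mark.parametrize("args", [(0, 480, 0.005), (75, -1, 0.005), (75, 480, 0)])
    def test_nonpositive_geometry_rejected(self, args):
        with pytest.raises(InvalidParameterError):
            ps.n_scans_for_diameter(*args)


class TestConfig:
    def test_default_grid_has_2048_points(self):
        assert ps.SynthConfig().grid.n_points == 2048

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ssc_mean": 20.0},  # outside [min, max]
            {"ssc_std": 0.0},
            {"pit_signal_attenuation": 1.5},
            {"pit_scatter_boost": -0.1},
            {"orientation_pathlength_ratio": 0.0},
            {"noise_sd": -1e-3},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ps.SynthConfig(**kwargs)


class TestGenerateFruit:
    def test_deterministic_under_fixed_seed(self):
        cfg = ps.SynthConfig(noise_sd=0.0, seed=3)
        a = ps.generate_fruit(cfg, "F", "O1", np.random.default_rng(99))
        b = ps.generate_fruit(cfg, "F", "O1", np.random.default_rng(99))
        np.testing.assert_array_equal(a.scans, b.scans)
        assert a.ssc_true == b.ssc_true

    def test_transmittance_nonnegative_and_on_grid(self, rng):
        cfg = ps.SynthConfig(noise_sd=5e-3)
        fs = ps.generate_fruit(cfg, "F", "O2", rng)
        assert fs.scans.shape[1] == cfg.grid.n_points
        assert np.all(fs.scans >= 0)

    def test_zone_effect_disabled_makes_zones_identical(self):
        cfg = ps.SynthConfig(
            pit_signal_attenuation=0.0, pit_scatter_boost=0.0, noise_sd=0.0,
            scatter_sigma=0.0,
        )
        fs = ps.generate_fruit(
            cfg, "F", "O1", np.random.default_rng(0), ssc_true=10.0, diameter_mm=72.0
        )
        # identical generative law: every scan equals every other
        assert np.all(fs.scans == fs.scans[0])

    def test_sugar_band_absorbance_increasing_in_ssc(self):
        # evaluate the noise-free generative law at the band centre and at
        # a band-free wavelength
        cfg = ps.SynthConfig(noise_sd=0.0, scatter_sigma=0.0)
        eff = FruitEffects(response=1.0)
        i910 = cfg.grid.index_of(910.0)
        i660 = cfg.grid.index_of(660.0)  # far outside every band
        prev = -np.inf
        values_at_660 = []
        for ssc in (8.0, 10.0, 12.0, 14.0):
            a = scan_absorbance(cfg, ssc, "O1", False, eff, cfg.diameter_mean_mm)
            assert a[i910] > prev
            prev = a[i910]
            values_at_660.append(a[i660])
        np.testing.assert_allclose(values_at_660, values_at_660[0], rtol=1e-6)

    def test_affine_in_ssc_at_band_centre(self):
        cfg = ps.SynthConfig(noise_sd=0.0, scatter_sigma=0.0)
        eff = FruitEffects(response=1.0)
        i910 = cfg.grid.index_of(910.0)
        vals = [
            scan_absorbance(cfg, s, "O1", False, eff, cfg.diameter_mean_mm)[i910]
            for s in (8.0, 10.0, 12.0)
        ]
        assert vals[2] - vals[1] == pytest.approx(vals[1] - vals[0], rel=1e-9)

    def test_orientation2_path_and_760_band(self):
        cfg = ps.SynthConfig()
        eff = FruitEffects(response=1.0)
        a1 = scan_absorbance(cfg, 10.0, "O1", False, eff, 75.0)
        a2 = scan_absorbance(cfg, 10.0, "O2", False, eff, 75.0)
        i760 = cfg.grid.index_of(760.0)
        i660 = cfg.grid.index_of(660.0)
        # path-length ratio scales absorbance everywhere ...
        assert a2[i660] == pytest.approx(a1[i660] * cfg.orientation_pathlength_ratio)
        # ... and the 760 nm water band is deepened beyond that ratio
        assert a2[i760] > a1[i760] * cfg.orientation_pathlength_ratio


class TestGenerateDataset:
    def test_split_counts(self, small_dataset, small_config):
        o1 = [f for f in small_dataset if f.orientation is ps.Orientation.O1]
        flags = [f.subset for f in o1]
        assert flags.count("calibration") == small_config.synth.n_calibration
        assert flags.count("validation") == small_config.synth.n_validation

    def test_identical_config_identical_dataset(self):
        cfg = ps.SynthConfig(n_fruit=6, n_calibration=4, n_validation=2, seed=11)
        d1 = ps.generate_dataset(cfg)
        d2 = ps.generate_dataset(cfg)
        assert [f.subset for f in d1] == [f.subset for f in d2]
        for a, b in zip(d1, d2):
            np.testing.assert_array_equal(a.scans, b.scans)

    def test_oversized_split_rejected(self):
        with pytest.raises(InvalidParameterError):
            ps.generate_dataset(
                ps.SynthConfig(n_fruit=5, n_calibration=4, n_validation=2)
            )

    def test_orientations_share_fruit_identity(self, small_dataset):
        by_id = {}
        for f in small_dataset:
            by_id.setdefault(f.sample_id, []).append(f)
        for sid, pair in by_id.items():
            assert {f.orientation for f in pair} == {ps.Orientation.O1, ps.Orientation.O2}
            assert pair[0].ssc_true == pair[1].ssc_true
            assert pair[0].diameter_mm == pair[1].diameter_mm

    def test_ssc_matches_truncated_normal_mean(self):
        # Monte-Carlo mean against the numerically exact truncated-normal
        # mean; small fruit keep the scan volume manageable
        cfg = ps.SynthConfig(
            n_fruit=1000, n_calibration=500, n_validation=500,
            diameter_mean_mm=14.0, diameter_std_mm=0.5,
            grid_start_nm=560.0, grid_stop_nm=1060.0, grid_step_nm=5.0,
            seed=21,
        )
        data = ps.generate_dataset(cfg, orientations=[ps.Orientation.O1])
        ssc = np.array([f.ssc_true for f in data])
        exact = truncated_ssc_mean(cfg)
        se = ssc.std(ddof=1) / np.sqrt(len(ssc))
        assert abs(ssc.mean() - exact) < 3 * se
        assert ssc.min() >= cfg.ssc_min and ssc.max() <= cfg.ssc_max

    def test_zone_contrast_with_pit_degradation(self):
        # with pit effects on, the middle zone's sugar-band signal is less
        # correlated with SSC than the outer zones' (>= 200 fruits)
        cfg = ps.SynthConfig(
            n_fruit=200, n_calibration=100, n_validation=100,
            diameter_mean_mm=36.0, diameter_std_mm=2.0, seed=33,
        )
        data = ps.generate_dataset(cfg, orientations=[ps.Orientation.O1])
        i910 = cfg.grid.index_of(910.0)
        i_ref = cfg.grid.index_of(660.0)
        ssc, mid, outer = [], [], []
        for f in data:
            split = ps.split_scan_counts(f.n_scans)
            absorb = -np.log10(np.clip(f.scans, 1e-12, None))
            sig = absorb[:, i910] - absorb[:, i_ref]  # de-baselined band depth
            ssc.append(f.ssc_true)
            mid.append(sig[split.indices(ps.Zone.S2)].mean())
            outer.append(
                np.concatenate(
                    [sig[split.indices(ps.Zone.S1)], sig[split.indices(ps.Zone.S3)]]
                ).mean()
            )
        r_mid = abs(np.corrcoef(ssc, mid)[0, 1])
        r_outer = abs(np.corrcoef(ssc, outer)[0, 1])
        assert r_mid < r_outer
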