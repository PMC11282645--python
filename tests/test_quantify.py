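import dataclasses

import numpy as np
import pytest

from csfdispersion.geometry import RegionMap, VolumeProfile
from csfdispersion.quantify import (
    AUCProfile,
    CalibrationMap,
    QuantConfig,
    SpatioTemporalMap,
    auc_profile,
    axial_concentration,
    build_spatiotemporal,
    fit_calibration,
    merge_exposures,
    percent_id_eacsf,
    region_mean_auc,
)
from csfdispersion.synthetic_data import (
    DEFAULT_PROTOCOLS,
    HIGH_CAMERA,
    LOW_CAMERA,
    ConcentrationField,
    calibration_stacks,
    render_frames,
    simulate_transport,
    TransportParams,
)

LEVELS = np.array([0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 50.0])


def _noise_free(cam):
    return dataclasses.replace(cam, noise_sd=0.0)


def _fit(cam, geometry, seed=0):
    stacks, lv = calibration_stacks(cam, LEVELS, geometry, seed=seed)
    return fit_calibration(stacks, lv, cam)


class TestFitCalibration:
    def test_linear_camera_round_trips_exactly(self, uniform_canal):
        cam = _noise_free(LOW_CAMERA)
        cal = _fit(cam, uniform_canal)
        for level in LEVELS:
            intensity = cam.offset + cam.gain * level
            assert cal(intensity) == pytest.approx(level, abs=1e-9)

    def test_saturating_camera_excludes_clipped_levels(self, uniform_canal):
        cal = _fit(_noise_free(HIGH_CAMERA), uniform_canal)
        # levels above the ~20 uM clip point are not in the map
        assert cal.concentrations.max() < 30.0
        assert cal.concentrations.max() >= 10.0

    def test_noisy_recovery_within_two_percent(self, uniform_canal):
        cam = HIGH_CAMERA
        cal = _fit(cam, uniform_canal, seed=21)
        for level in (1.0, 5.0, 10.0, 15.0):
            intensity = cam.offset + cam.gain * level
            assert cal(intensity) == pytest.approx(level, rel=0.02, abs=0.02)

    def test_single_level_rejected(self, uniform_canal):
        stacks, lv = calibration_stacks(LOW_CAMERA, np.array([5.0]),
                                        uniform_canal)
        with pytest.raises(ValueError, match="two calibration levels"):
            fit_calibration(stacks, lv, LOW_CAMERA)

    def test_non_monotone_means_named(self, uniform_canal):
        cam = _noise_free(LOW_CAMERA)
        stacks, lv = calibration_stacks(cam, np.array([0.0, 10.0, 20.0]),
                                        uniform_canal)
        stacks[1], stacks[2] = stacks[2], stacks[1]  # break monotonicity
        with pytest.raises(ValueError, match="not strictly increasing"):
            fit_calibration(stacks, lv, cam)


class TestAxialConcentration:
    def test_uniform_frame(self):
        cal = CalibrationMap(np.array([100.0, 200.0]), np.array([0.0, 10.0]),
                             "low")
        frame = np.full((5, 8), 150.0)
        assert np.allclose(axial_concentration(frame, cal), 5.0)

    def test_averaging_precedes_mapping(self):
        """With a kinked map, mean-then-map differs from map-then-mean."""
        cal = CalibrationMap(np.array([0.0, 100.0, 110.0]),
                             np.array([0.0, 10.0, 50.0]), "low")
        frame = np.empty((1, 2))
        frame[0] = [90.0, 110.0]  # mean 100 -> 10 uM
        assert axial_concentration(frame, cal)[0] == pytest.approx(10.0)
        per_pixel_then_mean = (cal(90.0) + cal(110.0)) / 2  # 29.5 uM
        assert per_pixel_then_mean != pytest.approx(10.0)

    def test_rendered_frame_round_trip(self, uniform_canal):
        cam = _noise_free(LOW_CAMERA)
        cal = _fit(cam, uniform_canal)
        rng = np.random.default_rng(2)
        c = rng.uniform(0, 45, uniform_canal.z_centers.size)
        field = ConcentrationField(
            z_centers=uniform_canal.z_centers, t_frames=np.array([0.0]),
            c=c[:, None],
        )
        stack = render_frames(field, uniform_canal, cam, seed=0)
        rec = axial_concentration(stack.frames[0], cal)
        assert np.allclose(rec, c, atol=1e-9)


class TestMergeExposures:
    def test_rule_with_tie_at_threshold(self):
        low = np.array([15.0, 9.9, 10.0])
        high = np.array([14.8, 9.7, 10.3])
        merged = merge_exposures(low, high, threshold=10.0)
        assert np.array_equal(merged, [15.0, 9.7, 10.0])  # tie keeps low

    def test_all_above_and_all_below(self):
        low = np.array([12.0, 30.0])
        high = np.array([11.0, 29.0])
        assert np.array_equal(merge_exposures(low, high, 10.0), low)
        assert np.array_equal(merge_exposures(low / 10, high, 10.0), high)

    def test_merge_is_idempotent(self):
        rng = np.random.default_rng(8)
        prof = rng.uniform(0, 30, 50)
        assert np.array_equal(merge_exposures(prof, prof, 10.0), prof)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            merge_exposures(np.zeros(3), np.zeros(4))


def _uniform_map(c_value, n_z=4, duration_h=3.0, frame_interval=30.0):
    n_t = int(duration_h * 3600 / frame_interval) + 1
    return SpatioTemporalMap(
        z_centers=np.arange(n_z) + 0.5,
        t_frames=np.arange(n_t) * frame_interval,
        c=np.full((n_z, n_t), float(c_value)),
    )


class TestBuildSpatiotemporal:
    def test_zero_field_stacks_give_zero_map(self, uniform_canal):
        low_cam, high_cam = _noise_free(LOW_CAMERA), _noise_free(HIGH_CAMERA)
        field = ConcentrationField(
            z_centers=uniform_canal.z_centers,
            t_frames=np.arange(3) * 30.0,
            c=np.zeros((uniform_canal.z_centers.size, 3)),
        )
        low = render_frames(field, uniform_canal, low_cam, seed=0)
        high = render_frames(field, uniform_canal, high_cam, seed=1)
        stmap = build_spatiotemporal(
            low, high, _fit(low_cam, uniform_canal), _fit(high_cam, uniform_canal),
            uniform_canal.z_centers,
        )
        assert np.allclose(stmap.c, 0.0, atol=1e-9)

    def test_matches_simulator_below_saturation(self, uniform_canal,
                                                default_waveform):
        """Noise-free pipeline recovers the ground-truth field to < 1%."""
        p = dataclasses.replace(DEFAULT_PROTOCOLS["2G2"], site_z=-40.0)
        field = simulate_transport(
            uniform_canal, default_waveform, p,
            TransportParams(production_site_z=10.0, absorption_site_z=15.0),
            duration=900.0, dt=0.5,
        )
        low_cam, high_cam = _noise_free(LOW_CAMERA), _noise_free(HIGH_CAMERA)
        low = render_frames(field, uniform_canal, low_cam, seed=0)
        high = render_frames(field, uniform_canal, high_cam, seed=1)
        stmap = build_spatiotemporal(
            low, high, _fit(low_cam, uniform_canal),
            _fit(high_cam, uniform_canal), uniform_canal.z_centers,
        )
        # the map is exact up to the top calibration level; beyond it the
        # low camera's readings clamp, as on the physical bench
        below = field.c < LEVELS.max()
        err = np.abs(stmap.c - field.c)[below]
        scale = np.maximum(field.c[below], 1.0)
        assert np.max(err / scale) < 0.01

    def test_frame_count_mismatch_rejected(self, uniform_canal):
        cam = _noise_free(LOW_CAMERA)
        make = lambda n: render_frames(
            ConcentrationField(
                z_centers=uniform_canal.z_centers,
                t_frames=np.arange(n) * 30.0,
                c=np.zeros((uniform_canal.z_centers.size, n)),
            ),
            uniform_canal, cam, seed=0,
        )
        cal = _fit(cam, uniform_canal)
        with pytest.raises(ValueError, match="frame counts differ"):
            build_spatiotemporal(make(3), make(4), cal, cal,
                                 uniform_canal.z_centers)


class TestAUC:
    def test_constant_map_rectangle(self):
        prof = auc_profile(_uniform_map(4.0), (0.0, 3.0))
        assert np.allclose(prof.auc, 12.0)

    def test_linear_ramp_triangle(self):
        n_t = 361
        t = np.arange(n_t) * 30.0
        c = np.tile(t / t[-1] * 6.0, (2, 1))  # 0 -> 6 uM over 3 h
        stmap = SpatioTemporalMap(z_centers=np.array([0.5, 1.5]), t_frames=t, c=c)
        prof = auc_profile(stmap, (0.0, 3.0))
        assert np.allclose(prof.auc, 6.0 * 3.0 / 2)

    def test_matches_refined_grid_oracle(self):
        rng = np.random.default_rng(12)
        t = np.arange(121) * 30.0
        c = rng.uniform(0, 20, (3, t.size))
        stmap = SpatioTemporalMap(z_centers=np.arange(3) + 0.5, t_frames=t, c=c)
        prof = auc_profile(stmap, (0.0, 1.0))
        # oracle: linear interpolation onto a 1 s grid, then integrate
        fine_t = np.arange(0, 3601)
        for i in range(3):
            fine_c = np.interp(fine_t, t, c[i])
            oracle = np.trapezoid(fine_c, fine_t / 3600.0)
            assert prof.auc[i] == pytest.approx(oracle, abs=1e-9)

    def test_additivity_on_shared_grid(self):
        rng = np.random.default_rng(13)
        t = np.arange(361) * 30.0
        c = rng.uniform(0, 20, (4, t.size))
        stmap = SpatioTemporalMap(z_centers=np.arange(4) + 0.5, t_frames=t, c=c)
        a01 = auc_profile(stmap, (0.0, 1.0)).auc
        a13 = auc_profile(stmap, (1.0, 3.0)).auc
        a03 = auc_profile(stmap, (0.0, 3.0)).auc
        assert np.allclose(a01 + a13, a03, atol=1e-12)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            auc_profile(_uniform_map(1.0), (2.0, 1.0))

    def test_window_outside_duration_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            auc_profile(_uniform_map(1.0, duration_h=1.0), (0.0, 3.0))


class TestPercentID:
    def _toy(self, volumes, conc):
        n = len(volumes)
        geom = VolumeProfile(z_centers=np.arange(n) + 0.5,
                             volumes=np.asarray(volumes, float))
        stmap = SpatioTemporalMap(
            z_centers=geom.z_centers,
            t_frames=np.array([0.0, 3 * 3600.0]),
            c=np.column_stack([np.zeros(n), np.asarray(conc, float)]),
        )
        return geom, stmap

    def test_hand_evaluated_example(self, regions):
        geom, stmap = self._toy([0.1, 0.2, 0.3], [10.0, 5.0, 2.0])
        pid = percent_id_eacsf(stmap, 3.0, geom, regions, 165.5)
        assert pid == pytest.approx((1 + 1 + 0.6) / 165.5 * 100, abs=1e-9)
        assert pid == pytest.approx(1.571, abs=5e-4)

    def test_uniform_distribution_closes_to_100(self, regions):
        volumes = [0.2, 0.3, 0.5]
        mass = 165.5
        conc = [mass / sum(volumes)] * 3
        geom, stmap = self._toy(volumes, conc)
        assert percent_id_eacsf(stmap, 3.0, geom, regions, mass) == pytest.approx(
            100.0
        )

    def test_zero_concentration_gives_zero(self, regions):
        geom, stmap = self._toy([0.1, 0.2], [0.0, 0.0])
        assert percent_id_eacsf(stmap, 3.0, geom, regions, 165.5) == 0.0

    def test_zero_injected_mass_rejected(self, regions):
        geom, stmap = self._toy([0.1], [1.0])
        with pytest.raises(ValueError, match="injected mass"):
            percent_id_eacsf(stmap, 3.0, geom, regions, 0.0)

    def test_monotone_in_eacsf_concentration(self, regions):
        geom, stmap = self._toy([0.1, 0.2, 0.3], [10.0, 5.0, 2.0])
        base = percent_id_eacsf(stmap, 3.0, geom, regions, 165.5)
        bumped = SpatioTemporalMap(
            z_centers=stmap.z_centers,
            t_frames=stmap.t_frames,
            c=stmap.c + np.array([[0.0, 1.0]]),
        )
        assert percent_id_eacsf(bumped, 3.0, geom, regions, 165.5) > base


class TestRegionMeanAUC:
    def _profile(self, aucs):
        return AUCProfile(z_centers=np.arange(len(aucs)) + 0.5,
                          auc=np.asarray(aucs, float), window_h=(0.0, 3.0))

    def test_constant_region(self, regions):
        prof = self._profile([3.0, 3.0, 3.0])
        assert region_mean_auc(prof, regions, "eacsf") == 3.0

    def test_two_slice_mean(self, regions):
        prof = self._profile([2.0, 4.0])
        assert region_mean_auc(prof, regions, "eacsf") == 3.0

    def test_matches_direct_mean_oracle(self, regions):
        rng = np.random.default_rng(4)
        aucs = rng.uniform(0, 10, 30)
        prof = self._profile(aucs)
        assert region_mean_auc(prof, regions, "eacsf") == pytest.approx(
            aucs.mean()
        )

    def test_empty_region_rejected(self, regions):
        prof = AUCProfile(z_centers=np.array([-100.5, -99.5]),
                          auc=np.array([1.0, 2.0]), window_h=(0.0, 3.0))
        with pytest.raises(ValueError, match="no slices"):
            region_mean_auc(prof, regions, "eacsf")

    def test_volume_weighted_option(self, regions):
        prof = self._profile([2.0, 4.0])
        geom = VolumeProfile(z_centers=np.array([0.5, 1.5]),
                             volumes=np.array([1.0, 3.0]))
        vw = region_mean_auc(prof, regions, "eacsf", geometry=geom,
                             volume_weighted=True)
        assert vw == pytest.approx((2 * 1 + 4 * 3) / 4)


class TestQuantConfig:
    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            QuantConfig(auc_windows=((0.0, 4.0),))
        with pytest.raises(ValueError):
            QuantConfig(merge_threshold=0.0)
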