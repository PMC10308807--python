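"""Ground-truth fidelity and determinism of the synthetic generators."""

import numpy as np
import pytest

from dropwet.fluids import WATER, MINIMAL_MEDIUM, BACTERIA_OD10
from dropwet.synthetic import (
    RampTargets,
    SyntheticScene,
    gen_cell_image,
    gen_evaporation_series,
    gen_flow_curve,
    gen_rotation_ramp,
    gen_sessile_image,
    noisy_linear_volumes,
)


class TestSessile:
    def test_ground_truth_volume_is_requested_volume(self, standard_drop):
        _, truth = standard_drop
        assert truth.volume_uL == 35.0
        assert truth.theta_left == truth.theta_right == 40.0

    def test_determinism_bit_identical(self):
        scene = SyntheticScene(noise_sd=5.0, seed=11)
        img1, _ = gen_sessile_image(20.0, 45.0, WATER, scene)
        img2, _ = gen_sessile_image(20.0, 45.0, WATER, scene)
        assert np.array_equal(img1, img2)

    def test_zero_gravity_half_disk(self):
        # V and theta=90 give a half disk of radius (3V/(2 pi))^(1/3)
        scene = SyntheticScene(pixel_scale=0.005)
        _, truth = gen_sessile_image(10.0, 90.0, WATER, scene, gravity=0.0)
        r_exp = (3.0 * 10.0 / (2.0 * np.pi)) ** (1.0 / 3.0)
        assert truth.height_mm == pytest.approx(r_exp, rel=1e-3)
        assert truth.length_mm == pytest.approx(2.0 * r_exp, rel=1e-3)

    def test_silhouette_area_matches_cross_section(self, standard_drop, default_scene):
        img, truth = standard_drop
        above = img[: default_scene.baseline_row].astype(float)
        area_px = ((230.0 - above) / (230.0 - 25.0)).sum()
        expected_px = truth.cross_section_mm2 / default_scene.pixel_scale**2
        # one boundary-pixel-equivalent per boundary pixel of slack
        n_boundary = int(np.sum((above > 30) & (above < 225)))
        assert abs(area_px - expected_px) <= max(n_boundary, 1)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            gen_sessile_image(-5.0, 40.0, WATER, SyntheticScene())
        with pytest.raises(ValueError):
            SyntheticScene(pixel_scale=-1.0)
        with pytest.raises(ValueError):
            SyntheticScene(baseline_row=900)


class TestEvaporationSeries:
    def test_volumes_exactly_affine(self):
        frames = gen_evaporation_series(
            29.9, -0.01, 300.0, 2400.0, "depinning", SyntheticScene(),
            MINIMAL_MEDIUM, render=False,
        )
        assert len(frames) == 9
        for f in frames:
            assert f.truth.volume_uL == pytest.approx(29.9 - 0.01 * f.time_s, abs=1e-9)
        assert frames[-1].truth.volume_uL == pytest.approx(5.9)

    def test_duration_violating_volume_floor_rejected(self):
        with pytest.raises(ValueError):
            gen_evaporation_series(
                29.9, -0.01, 300.0, 3000.0, "depinning", SyntheticScene(),
                MINIMAL_MEDIUM, render=False,
            )

    def test_zero_slope_frames_identical(self):
        frames = gen_evaporation_series(
            35.0, 0.0, 300.0, 900.0, "pinned", SyntheticScene(),
            BACTERIA_OD10, render=False,
        )
        g0 = frames[0].truth
        for f in frames[1:]:
            assert f.truth.length_mm == pytest.approx(g0.length_mm, abs=1e-9)
            assert f.truth.theta_left == pytest.approx(g0.theta_left, abs=1e-6)

    def test_pinned_mode_keeps_length_constant(self):
        frames = gen_evaporation_series(
            35.0, -0.0056, 300.0, 3000.0, "pinned", SyntheticScene(),
            BACTERIA_OD10, render=False,
        )
        L = np.array([f.truth.length_mm for f in frames])
        theta = np.array([f.truth.theta_left for f in frames])
        assert np.allclose(L, L[0], atol=1e-3)
        assert np.all(np.diff(theta) < 0)

    def test_depinning_mode_holds_theta_and_shrinks_length(self):
        frames = gen_evaporation_series(
            29.9, -0.01, 300.0, 2400.0, "depinning", SyntheticScene(),
            MINIMAL_MEDIUM, theta_depin_deg=25.0, render=False,
        )
        theta = np.array([f.truth.theta_left for f in frames])
        L = np.array([f.truth.length_mm for f in frames])
        clamped = theta <= 25.0 + 1e-6
        assert clamped.any()
        k0 = int(np.argmax(clamped))
        assert np.allclose(theta[k0:], 25.0, atol=1e-3)
        assert np.all(np.diff(L[k0:]) < 0)


class TestRotationRamp:
    def test_frame_count_one_per_rpm(self):
        frames = gen_rotation_ramp(
            RampTargets(), SyntheticScene(), WATER, ramp_rate_rpm_per_s=1.0,
            rs_max_rpm=100.0, render=False,
        )
        rs = [f.rs_rpm for f in frames]
        assert len(frames) == 101
        assert np.allclose(np.diff(rs), 1.0)

    def test_rear_edge_fixed_before_sliding_onset(self):
        frames = gen_rotation_ramp(
            RampTargets(rs_slide_rpm=50.0), SyntheticScene(), WATER, render=False
        )
        for f in frames:
            if f.rs_rpm < 50.0:
                assert f.truth.edge_left_mm == pytest.approx(
                    frames[0].truth.edge_left_mm, abs=1e-9
                )

    def test_pinned_rear_never_moves(self):
        frames = gen_rotation_ramp(
            RampTargets(rs_slide_rpm=None), SyntheticScene(), WATER, render=False
        )
        rear = np.array([f.truth.edge_left_mm for f in frames])
        assert np.allclose(rear, rear[0], atol=1e-12)

    def test_angle_plateaus_reach_targets(self):
        frames = gen_rotation_ramp(RampTargets(), SyntheticScene(), WATER, render=False)
        front = np.array([f.theta_front for f in frames])
        rear = np.array([f.theta_rear for f in frames])
        rs = np.array([f.rs_rpm for f in frames])
        assert np.allclose(front[rs >= 40.0], 53.0)
        assert np.allclose(rear[rs >= 50.0], 15.0)

    def test_negative_hysteresis_rejected(self):
        with pytest.raises(ValueError):
            RampTargets(theta_adv_deg=20.0, theta_rec_deg=30.0)


class TestFlowCurve:
    def test_newtonian_limit_constant_viscosity(self):
        curve = gen_flow_curve(0.05, 1.0)
        assert np.allclose(curve.viscosity, 0.05)

    def test_shear_thinning_decade_ratio(self):
        # n = 0.4 over 10-100 1/s: eta(100)/eta(10) = 10**-0.6
        curve = gen_flow_curve(0.05, 0.4, (10.0, 100.0))
        assert curve.viscosity[-1] / curve.viscosity[0] == pytest.approx(
            10.0**-0.6, rel=1e-9
        )

    def test_seed_reproducibility(self):
        c1 = gen_flow_curve(0.05, 0.5, noise_rel=0.05, seed=3)
        c2 = gen_flow_curve(0.05, 0.5, noise_rel=0.05, seed=3)
        assert np.array_equal(c1.viscosity, c2.viscosity)


class TestCellField:
    def test_blank_field(self):
        img, truth = gen_cell_image(0, 0, seed=1)
        assert truth.n_green == truth.n_red == 0
        assert img.max() == 10

    def test_counts_exact_by_construction(self):
        img, truth = gen_cell_image(50, 20, seed=5)
        assert truth.n_green == 50 and truth.n_red == 20
        assert len([o for o in truth.objects if o[0] == 0]) == 50

    def test_areas_within_range_and_units(self):
        _, truth = gen_cell_image(30, 10, seed=2, pixel_scale_um=0.566)
        areas = np.array([o[3] for o in truth.objects])
        assert np.all((areas >= 10) & (areas <= 30))
        areas_um2 = areas * 0.566**2
        assert np.all((areas_um2 >= 10 * 0.566**2) & (areas_um2 <= 30 * 0.566**2))

    def test_overcrowded_field_rejected(self):
        with pytest.raises(ValueError):
            gen_cell_image(2000, 2000, field_px=(64, 64))


def test_noisy_linear_volumes_noiseless_is_exact_line():
    t = np.arange(0.0, 3001.0, 300.0)
    v = noisy_linear_volumes(29.9, -0.01, t, 0.0, seed=0)
    assert np.allclose(v, 29.9 - 0.01 * t)
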