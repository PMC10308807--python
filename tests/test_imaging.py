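"""Round-trip accuracy of baseline, contour and contact-angle extraction."""

import numpy as np
import pytest

from dropwet.fluids import WATER
from dropwet.imaging import (
    ImagingError,
    contact_angles,
    detect_baseline,
    extract_profile,
    measure_frame,
    top_contour,
)
from dropwet.synthetic import (
    SyntheticScene,
    gen_asymmetric_sessile_image,
    gen_footprint_image,
    gen_sessile_image,
)


class TestBaseline:
    def test_round_trip(self, standard_drop, default_scene):
        img, _ = standard_drop
        assert abs(detect_baseline(img) - default_scene.baseline_row) <= 1

    def test_uniform_image_fails(self):
        with pytest.raises(ImagingError):
            detect_baseline(np.full((100, 100), 128, dtype=np.uint8))

    def test_robust_to_noise(self, default_scene):
        rows = []
        for sd in (0.0, 5.0):
            scene = SyntheticScene(noise_sd=sd, seed=9)
            img, _ = gen_sessile_image(35.0, 40.0, WATER, scene)
            rows.append(detect_baseline(img))
        assert abs(rows[0] - rows[1]) <= 1


class TestProfile:
    def test_contour_mad_below_one_pixel(self, standard_drop, default_scene):
        from dropwet.drop_shape import shape_metrics, solve_for

        img, truth = standard_drop
        prof = extract_profile(
            img, default_scene.baseline_row, default_scene.pixel_scale
        )
        shp = solve_for(35.0, 40.0, WATER)
        h = shape_metrics(shp, 40.0).height_mm
        center = 0.5 * (truth.edge_left_mm + truth.edge_right_mm)
        _, _, rr, zr = prof.flanks()
        sel = zr <= 0.95 * h
        model = np.interp((h - zr[sel]) * 1e-3, shp.z, shp.x) * 1e3
        mad = np.mean(np.abs((rr[sel] - center) - model))
        assert mad < default_scene.pixel_scale

    def test_edges_within_two_pixels(self, standard_drop, default_scene):
        img, truth = standard_drop
        geom, _ = measure_frame(img, default_scene.pixel_scale)
        tol = 2.0 * default_scene.pixel_scale
        assert abs(geom.edge_left_mm - truth.edge_left_mm) < tol
        assert abs(geom.edge_right_mm - truth.edge_right_mm) < tol

    def test_blank_region_fails(self):
        img = np.full((200, 200), 230, dtype=np.uint8)
        img[150:, :] = 80
        with pytest.raises(ImagingError):
            extract_profile(img, 150, 0.015)


class TestContactAngles:
    def test_symmetric_40deg_round_trip(self, standard_drop, default_scene):
        img, _ = standard_drop
        geom, _ = measure_frame(img, default_scene.pixel_scale)
        assert geom.theta_left == pytest.approx(40.0, abs=2.0)
        assert geom.theta_right == pytest.approx(40.0, abs=2.0)

    def test_semicircular_profile_is_90deg(self):
        scene = SyntheticScene(pixel_scale=0.005)
        img, _ = gen_sessile_image(2.0 * np.pi / 3.0, 90.0, WATER, scene, gravity=0.0)
        geom, _ = measure_frame(img, scene.pixel_scale)
        assert geom.theta_left == pytest.approx(90.0, abs=2.0)
        assert geom.theta_right == pytest.approx(90.0, abs=2.0)

    def test_asymmetric_drop_recovered(self, fine_scene):
        img, truth = gen_asymmetric_sessile_image(35.0, 20.0, 6.0, fine_scene)
        geom, _ = measure_frame(img, fine_scene.pixel_scale)
        assert geom.theta_left == pytest.approx(35.0, abs=2.0)
        assert geom.theta_right == pytest.approx(20.0, abs=2.0)

    @pytest.mark.parametrize("noise_sd", [0.0, 5.0])
    def test_round_trip_invariant_with_noise(self, noise_sd, default_scene):
        scene = SyntheticScene(noise_sd=noise_sd, seed=21)
        img, truth = gen_sessile_image(35.0, 40.0, WATER, scene)
        geom, _ = measure_frame(img, scene.pixel_scale)
        tol_mm = 2.0 * scene.pixel_scale
        assert abs(geom.theta_left - truth.theta_left) <= 2.0
        assert abs(geom.theta_right - truth.theta_right) <= 2.0
        assert abs(geom.length_mm - truth.length_mm) <= tol_mm
        assert abs(geom.height_mm - truth.height_mm) <= tol_mm


class TestInvariances:
    def test_mirror_equivariance(self, fine_scene):
        img, _ = gen_asymmetric_sessile_image(35.0, 20.0, 6.0, fine_scene)
        g, _ = measure_frame(img, fine_scene.pixel_scale)
        gm, _ = measure_frame(img[:, ::-1], fine_scene.pixel_scale)
        assert gm.theta_left == pytest.approx(g.theta_right, abs=1e-6)
        assert gm.theta_right == pytest.approx(g.theta_left, abs=1e-6)
        assert gm.length_mm == pytest.approx(g.length_mm, abs=1e-6)

    def test_pixel_scale_covariance(self):
        # same physical drop imaged at two magnifications
        g = {}
        for px, cols in ((0.0075, 1200), (0.015, 720)):
            scene = SyntheticScene(
                pixel_scale=px, image_size=(480, cols), baseline_row=420
            )
            img, _ = gen_sessile_image(35.0, 40.0, WATER, scene)
            g[px], _ = measure_frame(img, scene.pixel_scale)
        assert g[0.0075].length_mm == pytest.approx(g[0.015].length_mm, abs=0.03)
        assert g[0.0075].theta_left == pytest.approx(g[0.015].theta_left, abs=1.0)


class TestTopView:
    def test_disk_area_and_perimeter(self, default_scene):
        img = gen_footprint_image(3.0, 3.0, default_scene)
        tc = top_contour(img, default_scene.pixel_scale)
        assert tc.area_mm2 == pytest.approx(np.pi * 9.0, rel=0.02)
        assert tc.perimeter_mm == pytest.approx(2.0 * np.pi * 3.0, rel=0.02)

    def test_elongated_footprint_aspect_ratio(self, default_scene):
        img = gen_footprint_image(3.0, 1.5, default_scene)
        tc = top_contour(img, default_scene.pixel_scale)
        rows, cols = tc.contour_mm[:, 0], tc.contour_mm[:, 1]
        aspect = (cols.max() - cols.min()) / (rows.max() - rows.min())
        assert aspect == pytest.approx(2.0, abs=0.05)

    def test_blank_image_fails(self):
        with pytest.raises(ImagingError):
            top_contour(np.full((100, 100), 230, dtype=np.uint8), 0.015)
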