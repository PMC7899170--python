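"""Calibrated measurement: central angles, law-of-cosines decomposition,
uniform baseline, and equivalence with the simulator's analytic inverse."""

import numpy as np
import pandas as pd
import pytest

from endocal import horizontal, measure
from endocal.camera import invert_pixel_radius, project_point
from endocal.segment import FOVGeometry


@pytest.fixture(scope="module")
def linear_model():
    """Exact F_{1,1} model: r_mm = 0.01 * w * r_p (pinhole-like camera)."""
    rows = [
        (rec, w, r_p, 0.01 * w * r_p)
        for rec, w in enumerate(np.linspace(2, 32, 16))
        for r_p in (20.0, 60.0, 110.0)
    ]
    samples = pd.DataFrame(rows, columns=horizontal.SAMPLE_COLUMNS)
    return horizontal.fit_nonuniform(samples, 1, 1)


class TestCentralAngle:
    def test_quarter_turn(self):
        assert measure.central_angle((1.0, 0.0), (0.0, 1.0)) == pytest.approx(90.0)

    def test_antipodal(self):
        assert measure.central_angle((1.0, 0.0), (-1.0, 1e-12)) == pytest.approx(
            180.0, abs=1e-6
        )

    def test_normalized_to_at_most_180(self):
        a = (np.cos(np.radians(10)), np.sin(np.radians(10)))
        b = (np.cos(np.radians(350)), np.sin(np.radians(350)))
        assert measure.central_angle(a, b) == pytest.approx(20.0, abs=1e-9)

    def test_endpoint_at_origin_rejected(self):
        with pytest.raises(ValueError):
            measure.central_angle((0.0, 0.0), (1.0, 1.0))


class TestRadial:
    def test_zero_length(self, linear_model):
        assert measure.measure_radial(linear_model, 10.0, 0.0) == 0.0

    def test_linear_model_scaling(self, linear_model):
        assert measure.measure_radial(linear_model, 10.0, 50.0) == pytest.approx(
            5.0, abs=1e-9
        )

    def test_innermost_circle_at_printed_anchor(self, camera, nonuniform_model):
        # 0.5 mm grid, w=2.87: innermost circle sits at ~34 px; the calibrated
        # surface must convert its radius back to ~0.5 mm
        from endocal.camera import pixel_radius

        r_px = pixel_radius(camera, 0.5, 2.87)
        est = measure.measure_radial(nonuniform_model, 2.87, r_px)
        assert est == pytest.approx(0.5, abs=0.05)

    def test_agrees_with_analytic_camera_inverse(self, camera, nonuniform_model):
        # numeric inversion of the forward projector as independent oracle
        for w in (3.0, 10.0, 20.0, 30.0):
            for r_px in (20.0, 60.0, 100.0, 125.0):
                truth = invert_pixel_radius(camera, r_px, w)
                est = measure.measure_radial(nonuniform_model, w, r_px)
                assert est == pytest.approx(truth, abs=0.05)


class TestGeneral:
    def test_coincident_endpoints(self, linear_model):
        res = measure.measure_general(linear_model, 10.0, (30.0, 40.0), (30.0, 40.0))
        assert res.length_mm == pytest.approx(0.0, abs=1e-9)

    def test_pythagorean_triangle(self, linear_model):
        # OA = 3 mm, OB = 4 mm at alpha = 90 deg -> AB = 5 mm
        res = measure.measure_general(linear_model, 10.0, (30.0, 0.0), (0.0, 40.0))
        assert res.oa_mm == pytest.approx(3.0, abs=1e-9)
        assert res.ob_mm == pytest.approx(4.0, abs=1e-9)
        assert res.alpha_deg == pytest.approx(90.0)
        assert res.length_mm == pytest.approx(5.0, abs=1e-9)

    def test_symmetric_in_endpoints(self, linear_model):
        a, b = (42.0, -17.0), (-88.0, 31.0)
        r1 = measure.measure_general(linear_model, 12.0, a, b)
        r2 = measure.measure_general(linear_model, 12.0, b, a)
        assert r1.length_mm == r2.length_mm

    def test_rotation_invariance_about_fov_center(self, nonuniform_model):
        a = np.array([50.0, 20.0])
        b = np.array([-30.0, 60.0])
        base = measure.measure_general(nonuniform_model, 15.0, a, b).length_mm
        for phi in (0.3, 1.1, 2.9):
            R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
            rot = measure.measure_general(nonuniform_model, 15.0, R @ a, R @ b)
            assert rot.length_mm == pytest.approx(base, abs=1e-9)

    def test_endpoint_at_center_falls_back_to_radial(self, linear_model):
        res = measure.measure_general(linear_model, 10.0, (0.0, 0.0), (40.0, 0.0))
        assert res.length_mm == pytest.approx(4.0, abs=1e-9)
        assert "FOV centre" in res.warnings[0]

    def test_triangle_inequality_for_collinear_scene_points(
        self, camera, nonuniform_model
    ):
        w = 18.0
        p, q, r = (np.array([-4.0, 1.0]), np.array([0.0, 1.0]), np.array([6.0, 1.0]))

        def px(pt):
            proj = project_point(camera, pt, w)
            return measure.to_centered(
                (proj.x, proj.y),
                FOVGeometry(center_px=camera.fov_center_px,
                            radius_px=camera.fov_radius_px),
            )

        pq = measure.measure_general(nonuniform_model, w, px(p), px(q)).length_mm
        qr = measure.measure_general(nonuniform_model, w, px(q), px(r)).length_mm
        pr = measure.measure_general(nonuniform_model, w, px(p), px(r)).length_mm
        assert pr <= pq + qr + 2 * 0.05

    def test_oracle_equivalence_against_simulator_inverse(
        self, camera, nonuniform_model, rng
    ):
        """With oracle w and oracle endpoint pixels, the law-of-cosines chain
        reproduces true mm lengths within 0.1 mm across lengths and distances."""
        fov = FOVGeometry(center_px=camera.fov_center_px,
                          radius_px=camera.fov_radius_px)
        theta_max = camera.theta_max()
        checked = 0
        for w in (3.0, 8.0, 15.0, 22.0, 30.0):
            r_limit = 0.9 * w * np.tan(theta_max)
            for length in (1.0, 5.0, 12.0, 20.0):
                if length > 1.6 * r_limit:
                    continue
                for _ in range(4):
                    ang = rng.uniform(0, 2 * np.pi)
                    c = rng.uniform(-0.5, 0.5, 2) * r_limit
                    half = 0.5 * length * np.array([np.cos(ang), np.sin(ang)])
                    a_mm, b_mm = c - half, c + half
                    if max(np.linalg.norm(a_mm), np.linalg.norm(b_mm)) > r_limit:
                        continue
                    if min(np.linalg.norm(a_mm), np.linalg.norm(b_mm)) < 0.2:
                        continue
                    pa = project_point(camera, a_mm, w)
                    pb = project_point(camera, b_mm, w)
                    res = measure.measure_general(
                        nonuniform_model, w, (pa.x, pa.y), (pb.x, pb.y), fov=fov
                    )
                    assert res.length_mm == pytest.approx(length, abs=0.1)
                    checked += 1
        assert checked > 30


class TestUniform:
    def test_coincident_endpoints(self):
        m = horizontal.UniformPixelSizeModel().fit(
            np.array([5.0, 30.0]), np.array([0.05, 0.2])
        )
        res = measure.measure_uniform(m, 10.0, (7.0, 7.0), (7.0, 7.0))
        assert res.length_mm == 0.0

    def test_scales_pixel_distance(self):
        m = horizontal.UniformPixelSizeModel().fit(
            np.array([0.0, 20.0]), np.array([0.1, 0.1])
        )
        res = measure.measure_uniform(m, 10.0, (0.0, 0.0), (30.0, 40.0))
        assert res.length_mm == pytest.approx(0.1 * 50.0, abs=1e-9)
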