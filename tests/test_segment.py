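"""Segmentation: preprocessing, FOV, circles, dots, lines, template frame."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endocal import segment, synth
from endocal.camera import default_projector
from endocal.pipeline import segment_circles


class TestPreprocess:
    def test_constant_frame_invariant(self):
        img = np.full((40, 40), 3.7)
        assert segment.preprocess([img]) == pytest.approx(img)

    def test_temporal_mean(self):
        a = np.full((20, 20), 1.0)
        b = np.full((20, 20), 3.0)
        assert segment.preprocess([a, b]) == pytest.approx(np.full((20, 20), 2.0))

    def test_impulse_matches_dense_convolution_oracle(self):
        img = np.zeros((65, 65))
        img[32, 32] = 1.0
        out = segment.preprocess([img], sigma=2.0)
        # brute-force oracle: explicit truncated Gaussian kernel, direct sum
        r = int(4.0 * 2.0 + 0.5)
        ax = np.arange(-r, r + 1)
        k1 = np.exp(-(ax**2) / (2 * 2.0**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        assert out[32, 32] == pytest.approx(kernel[r, r], rel=1e-6)
        assert out[32, 35] == pytest.approx(kernel[r, r + 3], rel=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            segment.preprocess([])


class TestEstimateFov:
    def test_recovers_synthetic_geometry(self, camera):
        img, truth = synth.render(
            camera, synth.SceneSpec("circular_grid", w_mm=6.0, spacing_mm=0.5)
        )
        fov = segment.estimate_fov(segment.preprocess([img]))
        assert fov.center_px[0] == pytest.approx(truth["fov"]["cx"], abs=1.0)
        assert fov.center_px[1] == pytest.approx(truth["fov"]["cy"], abs=1.0)
        assert fov.radius_px == pytest.approx(truth["fov"]["radius_px"], abs=1.0)

    def test_fiducial_angle_detected(self, camera):
        from endocal.camera import default_camera

        for angle in (0.0, 30.0, 117.0):
            cam = default_camera(fiducial_angle_deg=angle)
            img, _ = synth.render(
                cam, synth.SceneSpec("circular_grid", w_mm=6.0, spacing_mm=0.5)
            )
            fov = segment.estimate_fov(segment.preprocess([img]))
            err = abs((fov.fiducial_angle_deg - angle + 180) % 360 - 180)
            assert err <= 2.0

    def test_fully_bright_image_raises(self):
        with pytest.raises(ValueError):
            segment.estimate_fov(np.ones((100, 100)))


class TestCircles:
    def test_coarse_radii_on_ideal_image(self, camera):
        img, truth = synth.render(
            camera, synth.SceneSpec("circular_grid", w_mm=10.0, spacing_mm=1.0)
        )
        pre = segment.preprocess([img])
        fov = segment.estimate_fov(pre)
        coarse = segment.detect_circles_coarse(pre, fov)
        true_r = [c["r_px"] for c in truth["circles"]]
        assert len(coarse) == len(true_r)
        for det, r in zip(coarse, true_r):
            assert det.radius_px == pytest.approx(r, abs=1.0)

    def test_innermost_spacing_matches_printed_anchor(self, camera):
        # 0.5 mm grid at w=2.87: the two smallest circles are ~30 px apart
        img, _ = synth.render(
            camera, synth.SceneSpec("circular_grid", w_mm=2.87, spacing_mm=0.5)
        )
        pre = segment.preprocess([img])
        fov = segment.estimate_fov(pre)
        coarse = segment.detect_circles_coarse(pre, fov)
        assert coarse[1].radius_px - coarse[0].radius_px == pytest.approx(30.0, abs=1.5)

    def test_refinement_within_half_pixel_of_truth(self, camera):
        img, truth = synth.render(
            camera, synth.SceneSpec("circular_grid", w_mm=20.0, spacing_mm=2.0)
        )
        _, refined = segment_circles(img)
        true_r = [c["r_px"] for c in truth["circles"]]
        assert len(refined) == len(true_r)
        for det, r in zip(refined, true_r):
            assert det.radius_px == pytest.approx(r, abs=0.5)
            assert det.stage == "refined"

    def test_refinement_never_worse_than_coarse_cost(self, camera):
        img, _ = synth.render(
            camera, synth.SceneSpec("circular_grid", w_mm=8.0, spacing_mm=0.5)
        )
        pre = segment.preprocess([img])
        fov = segment.estimate_fov(pre)
        grad = segment.gradient_magnitude(pre)
        for c in segment.detect_circles_coarse(pre, fov):
            ref = segment.refine_circle(pre, c, gradient=grad)
            # cost at the coarse parameters is one of the searched candidates
            cx, cy = c.center_px
            ys, xs = np.mgrid[0 : pre.shape[0], 0 : pre.shape[1]]
            ring = np.abs(np.hypot(xs - cx, ys - cy) - c.radius_px) <= 0.5
            assert ref.cost <= grad[ring].sum() + 1e-9

    def test_refinement_offsets_recovered(self, camera):
        # perturb a truth-seeded detection; refinement must come back
        img, truth = synth.render(
            camera, synth.SceneSpec("circular_grid", w_mm=15.0, spacing_mm=1.0)
        )
        pre = segment.preprocess([img])
        cx, cy = truth["fov"]["cx"], truth["fov"]["cy"]
        r = truth["circles"][2]["r_px"]
        seed = segment.CircleDetection(center_px=(cx + 1.0, cy - 1.0),
                                       radius_px=r + 0.75)
        ref = segment.refine_circle(pre, seed)
        assert ref.radius_px == pytest.approx(r, abs=0.5)

    def test_ring_mask_pixel_count_tracks_circumference(self):
        # sub-pixel centre, as produced by the 0.25 px refinement lattice
        ys, xs = np.mgrid[0:200, 0:200]
        d = np.hypot(xs - 100.25, ys - 99.75)
        for r in (10.0, 17.25, 30.0, 70.0):
            count = int(np.sum(np.abs(d - r) <= 0.5))
            assert count == pytest.approx(2 * np.pi * r, rel=0.10)


class TestLaserDots:
    def test_detection_accuracy_and_labels(self, camera, projector):
        img, truth = synth.render(
            camera, synth.SceneSpec("laser_frame", w_mm=9.0), projector=projector
        )
        pre = segment.preprocess([img])
        fov = segment.estimate_fov(pre)
        dots = segment.detect_laser_dots(pre, fov)
        pos = dots.positions()
        visible = [d for d in truth["dots"] if d["in_fov"]]
        assert np.isfinite(pos[:, 0]).sum() == len(visible)
        for d in visible:
            err = np.hypot(pos[d["index"] - 1, 0] - d["x"],
                           pos[d["index"] - 1, 1] - d["y"])
            assert err <= 0.3

    def test_blank_frame_all_absent(self, camera):
        img, _ = synth.render(camera, synth.SceneSpec("laser_frame", w_mm=9.0),
                              projector=default_projector())
        blank = np.where(img >= 0.1, 0.25, 0.02)  # uniform interior, no spots
        fov = segment.estimate_fov(blank)
        dots = segment.detect_laser_dots(blank, fov)
        assert all(not d.present for d in dots.dots)

    def test_labels_follow_fiducial_under_rotation(self, camera, projector):
        """Rotating the whole camera (fiducial + pattern) keeps dot labels."""
        img, _ = synth.render(
            camera, synth.SceneSpec("laser_frame", w_mm=12.0), projector=projector
        )
        pre = segment.preprocess([img])
        fov = segment.estimate_fov(pre)
        base = segment.detect_laser_dots(pre, fov)
        rot = np.rot90(pre, k=-1)  # 90 deg clockwise in storage
        fov_r = segment.estimate_fov(rot)
        rotated = segment.detect_laser_dots(rot, fov_r)
        # fiducial angle moves by 90 deg, so labelling must be unchanged
        h = pre.shape[0]
        for d, dr in zip(base.dots, rotated.dots):
            assert d.present == dr.present
            if d.present:
                x, y = d.position_px
                # storage rot90(k=-1): (x, y) -> (h - 1 - y, x)
                assert dr.position_px[0] == pytest.approx(h - 1 - y, abs=0.35)
                assert dr.position_px[1] == pytest.approx(x, abs=0.35)


class TestRadialLines:
    def test_single_horizontal_line(self, camera):
        img, _ = synth.render(
            camera,
            synth.SceneSpec("line_segment", w_mm=10.0,
                            endpoints_mm=((-6.0, 0.0), (6.0, 0.0))),
        )
        pre = segment.preprocess([img])
        fov = segment.estimate_fov(pre)
        with pytest.warns(UserWarning):
            angles = segment.detect_radial_lines(pre, fov)
        assert len(angles) >= 1
        assert min(angles[0], 180 - angles[0]) == pytest.approx(0.0, abs=1.0)

    def test_sector_grid_recovers_12_lines(self, set3_records):
        rec = set3_records[1]
        pre = segment.preprocess([rec["image"]])
        fov = segment.estimate_fov(pre)
        angles = segment.detect_radial_lines(pre, fov)
        truth = np.asarray(rec["truth"]["sector_angles_deg"])
        assert len(angles) == 12
        err = np.abs(((angles - truth + 90) % 180) - 90)
        assert err.max() <= 2.0


class TestTemplateNormalization:
    def test_identity_when_fiducial_at_standard_angle(self):
        fov = segment.FOVGeometry(center_px=(100.0, 100.0), radius_px=135.0,
                                  fiducial_angle_deg=30.0)
        pts = np.array([[120.0, 90.0], [80.0, 130.0]])
        out = segment.normalize_to_template(pts, fov, standard_angle_deg=30.0)
        expected = np.column_stack([pts[:, 0] - 100.0, 100.0 - pts[:, 1]])
        assert out == pytest.approx(expected, abs=1e-9)

    def test_fiducial_ray_maps_to_standard_angle(self):
        fov = segment.FOVGeometry(center_px=(100.0, 100.0), radius_px=100.0,
                                  fiducial_angle_deg=75.0)
        a = np.radians(75.0)
        p = (100.0 + 50 * np.cos(a), 100.0 - 50 * np.sin(a))  # on fiducial ray
        out = segment.normalize_to_template(p, fov, standard_angle_deg=20.0,
                                            reference_radius_px=135.0)
        ang = np.degrees(np.arctan2(out[1], out[0]))
        assert ang == pytest.approx(20.0, abs=1e-9)
        assert np.hypot(*out) == pytest.approx(50 * 1.35, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        x=st.floats(-200, 200), y=st.floats(-200, 200),
        fid=st.floats(0, 360), std=st.floats(0, 360),
        r=st.floats(50, 200),
    )
    def test_round_trip_is_identity(self, x, y, fid, std, r):
        fov = segment.FOVGeometry(center_px=(144.0, 140.0), radius_px=r,
                                  fiducial_angle_deg=fid)
        t = segment.normalize_to_template((x, y), fov, std)
        back = segment.denormalize_from_template(t, fov, std)
        assert back == pytest.approx(np.array([x, y]), abs=1e-9)

    def test_zero_radius_rejected(self):
        with pytest.raises(ValueError):
            segment.FOVGeometry(center_px=(0, 0), radius_px=0.0)
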