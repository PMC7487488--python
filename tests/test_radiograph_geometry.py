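"""Landmark constructions on the AP radiograph."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from femwba import (
    DegenerateGeometryError,
    MissingLandmarkError,
    ParameterError,
    RadiographLandmarkSet,
    build_boundary_construction,
    ce_angle,
    correct_magnification,
    lateral_margin_line,
    medial_margin_line,
)
from femwba.radiograph_geometry import fit_circle


def angle_between(u, v):
    return math.acos(
        np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
    )


class TestMagnificationCorrection:
    def test_scales_points_by_marker_ratio(self):
        lm = RadiographLandmarkSet(
            points={"p1": np.array([110.0, 220.0])},
            marker_measured_diameter=27.5,
            marker_true_diameter=25.0,
        )
        out = correct_magnification(lm)
        assert np.allclose(out["p1"], [100.0, 200.0])
        assert out.marker_measured_diameter == out.marker_true_diameter

    def test_identity_when_marker_matches(self):
        lm = RadiographLandmarkSet(points={"p1": np.array([3.0, 4.0])})
        out = correct_magnification(lm)
        assert np.allclose(out["p1"], lm["p1"])

    def test_idempotent_after_marker_update(self):
        lm = RadiographLandmarkSet(
            points={"p1": np.array([12.0, -7.0])},
            marker_measured_diameter=30.0,
        )
        once = correct_magnification(lm)
        twice = correct_magnification(once)
        assert np.allclose(once["p1"], twice["p1"])

    def test_rejects_nonpositive_marker(self):
        with pytest.raises(ParameterError):
            RadiographLandmarkSet(points={}, marker_measured_diameter=0.0)


class TestLateralMarginLine:
    def test_symmetric_right_angle_bisector(self):
        line = lateral_margin_line((0, 0), (1, 0), (0, 1))
        assert np.allclose(line.direction, [math.sqrt(2) / 2, math.sqrt(2) / 2])

    def test_half_of_45_degrees(self):
        line = lateral_margin_line((0, 0), (2, 0), (2, 2))
        ang = math.degrees(math.atan2(line.direction[1], line.direction[0]))
        assert ang == pytest.approx(22.5, abs=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            lateral_margin_line((1, 1), (1, 1), (0, 2))

    def test_opposite_rays_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            lateral_margin_line((0, 0), (1, 0), (-1, 0))

    def test_equal_angles_over_seeded_samples(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p4, p7, p11 = rng.uniform(-50, 50, size=(3, 2))
            if min(np.linalg.norm(p7 - p4), np.linalg.norm(p11 - p4)) < 1e-3:
                continue
            u1, u2 = p7 - p4, p11 - p4
            if np.linalg.norm(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)) < 1e-3:
                continue
            line = lateral_margin_line(p4, p7, p11)
            a1 = angle_between(line.direction, u1)
            a2 = angle_between(line.direction, u2)
            assert abs(a1 - a2) < 1e-12


class TestMedialMarginLine:
    def test_vertical_line_through_midpoint(self):
        line, W = medial_margin_line((1, 5), (0, 0), (2, 0))
        assert np.allclose(W, [1, 0])
        assert np.allclose(line.direction, [0, -1])

    def test_midpoint_of_coincident_points(self):
        _, W = medial_margin_line((0, 0), (3, 4), (3, 4))
        assert np.allclose(W, [3, 4])

    def test_p5_equal_to_w_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            medial_margin_line((1, 0), (0, 0), (2, 0))


class TestCEAngle:
    def test_superior_point_is_zero(self):
        assert ce_angle((0, 0), (0, 10), "left") == pytest.approx(0.0, abs=1e-12)

    def test_equal_offsets_is_45(self):
        assert ce_angle((0, 0), (10, 10), "left") == pytest.approx(45.0, abs=1e-12)

    def test_lateral_sense_depends_on_side(self):
        assert ce_angle((0, 0), (10, 10), "right") == pytest.approx(-45.0, abs=1e-12)

    def test_mirror_preserves_ce(self):
        lm = RadiographLandmarkSet(
            points={"p19": np.array([5.0, 2.0]), "p4": np.array([20.0, 25.0])},
            side="left",
        )
        mirrored = lm.mirrored()
        a = ce_angle(lm["p19"], lm["p4"], lm.side)
        b = ce_angle(mirrored["p19"], mirrored["p4"], mirrored.side)
        assert a == pytest.approx(b, abs=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            ce_angle((1, 1), (1, 1), "left")


class TestBoundaryConstruction:
    def test_lines_pass_through_defining_points(self, radiograph_noise_free):
        lm = correct_magnification(radiograph_noise_free)
        bc = build_boundary_construction(lm)
        assert np.allclose(bc.lateral_line.anchor, lm["p4"])
        assert np.allclose(bc.W, 0.5 * (lm["p6"] + lm["p18"]))
        # W lies on the medial line
        t = (bc.W - bc.medial_line.anchor) @ bc.medial_line.direction
        assert np.linalg.norm(bc.medial_line.point_at(t) - bc.W) < 1e-9

    def test_missing_landmark_is_named(self, radiograph_noise_free):
        lm = correct_magnification(radiograph_noise_free)
        del lm.points["p18"]
        with pytest.raises(MissingLandmarkError) as exc:
            build_boundary_construction(lm)
        assert exc.value.landmark == "p18"

    def test_mirrored_landmarks_mirror_the_construction(self, radiograph_noise_free):
        lm = correct_magnification(radiograph_noise_free)
        bc = build_boundary_construction(lm)
        bcm = build_boundary_construction(lm.mirrored())
        assert np.allclose(bcm.W, [-bc.W[0], bc.W[1]], atol=1e-9)
        assert np.allclose(
            np.abs(bcm.lateral_line.direction),
            np.abs([bc.lateral_line.direction[0], bc.lateral_line.direction[1]]),
            atol=1e-9,
        )

    @settings(max_examples=25, deadline=None, derandomize=True, database=None)
    @given(
        angle=st.floats(-180, 180),
        tx=st.floats(-100, 100),
        ty=st.floats(-100, 100),
    )
    def test_rigid_motion_equivariance(self, radiograph_noise_free, angle, tx, ty):
        """Rotating/translating all landmarks moves the lines identically."""
        lm = correct_magnification(radiograph_noise_free)
        bc = build_boundary_construction(lm)
        moved = lm.transformed(angle, (tx, ty))
        bcm = build_boundary_construction(moved)
        a = math.radians(angle)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        assert np.allclose(bcm.lateral_line.anchor, R @ bc.lateral_line.anchor + (tx, ty), atol=1e-8)
        assert np.allclose(bcm.lateral_line.direction, R @ bc.lateral_line.direction, atol=1e-10)
        assert np.allclose(bcm.W, R @ bc.W + (tx, ty), atol=1e-8)


class TestCircleFitCrossCheck:
    def test_head_contour_points_recover_head_center(self, radiograph_noise_free):
        """p3/p6/p16 lie on the head circle, so their fit lands near p19."""
        lm = correct_magnification(radiograph_noise_free)
        center, radius, rms = fit_circle([lm["p3"], lm["p6"], lm["p16"]])
        assert np.allclose(center, lm["p19"], atol=1e-9)
        assert rms < 1e-9
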