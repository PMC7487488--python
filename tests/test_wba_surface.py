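"""Weight-bearing patch trimming on spheres with closed-form answers."""
import math

import numpy as np
import pytest
import trimesh

from femwba import (
    EmptyPatchError,
    FitFailureError,
    WeightBearingPatch,
    apply_inferior_limit,
    coronal_plane,
    fit_head_sphere,
    monte_carlo_patch_area,
    patch_area,
    smooth_patch_boundary,
    trim_by_margin_lines,
)
from femwba.registration_projection import Line3D
from femwba.wba_surface import elevation_mask, halfspace_mask

PLANE = coronal_plane()
UP = np.array([0.0, 0.0, 1.0])


def sphere_head(mesh):
    return fit_head_sphere(mesh, hint_point=(0.0, 0.0, 1.0), hint_radius=3.0)


def line3(anchor_xz, direction_xz):
    """A margin line in the coronal datum plane from 2D (x, z) data."""
    a = np.array([anchor_xz[0], 0.0, anchor_xz[1]])
    d = np.array([direction_xz[0], 0.0, direction_xz[1]])
    return Line3D(point=a, direction=d)


class TestSphereFit:
    def test_exact_unit_sphere(self, unit_sphere):
        head = sphere_head(unit_sphere)
        assert np.linalg.norm(head.center) < 1e-9
        assert head.radius == pytest.approx(1.0, abs=1e-9)
        assert head.fit_rms < 1e-9
        assert len(head.head_facets) == len(unit_sphere.faces)

    def test_plane_mesh_fails(self):
        g = trimesh.creation.box(extents=(40, 40, 0.5))
        with pytest.raises(FitFailureError):
            fit_head_sphere(g, hint_point=(0, 0, 0.25), hint_radius=50.0)


class TestSphericalTrims:
    def test_full_sphere_limit_90(self, unit_sphere_coarse):
        head = sphere_head(unit_sphere_coarse)
        patch = apply_inferior_limit(head.head_facets, head, UP, limit_deg=90.0)
        assert patch.area == pytest.approx(4 * math.pi, rel=0.01)

    def test_hat_box_zone_limit_30(self, unit_sphere):
        """Zone above latitude -30 deg has area 2*pi*r*h = 3*pi (Archimedes)."""
        head = sphere_head(unit_sphere)
        patch = apply_inferior_limit(head.head_facets, head, UP, limit_deg=30.0)
        assert patch.area == pytest.approx(3 * math.pi, rel=0.01)

    def test_half_sphere_from_central_vertical_line(self, unit_sphere):
        head = sphere_head(unit_sphere)
        med = line3((0.0, 0.0), (0.0, 1.0))
        kept = trim_by_margin_lines(
            head, None, med, PLANE, side_point=(0.5, 0.0, 0.0)
        )
        area = float(head.mesh.area_faces[kept].sum())
        assert area == pytest.approx(2 * math.pi, rel=0.02)

    def test_lune_60_degrees(self, unit_sphere):
        """Wedge between two central planes at 60 deg: area 2*theta*r^2."""
        head = sphere_head(unit_sphere)
        l1 = line3((0.0, 0.0), (1.0, 0.0))
        ang = math.radians(60.0)
        l2 = line3((0.0, 0.0), (math.cos(ang), math.sin(ang)))
        mid = math.radians(30.0)
        side_point = (math.cos(mid), 0.0, math.sin(mid))
        kept = trim_by_margin_lines(head, l1, l2, PLANE, side_point=side_point)
        patch = apply_inferior_limit(kept, head, UP, limit_deg=90.0)
        assert patch.area == pytest.approx(2 * ang, rel=0.01)

    def test_far_away_lines_keep_everything(self, unit_sphere_coarse):
        head = sphere_head(unit_sphere_coarse)
        lat = line3((5.0, 0.0), (0.0, 1.0))
        med = line3((-5.0, 0.0), (0.0, 1.0))
        kept = trim_by_margin_lines(head, lat, med, PLANE)
        assert len(kept) == len(head.head_facets)

    def test_empty_result_names_the_constraint(self, unit_sphere_coarse):
        head = sphere_head(unit_sphere_coarse)
        lat = line3((5.0, 0.0), (0.0, 1.0))
        with pytest.raises(EmptyPatchError) as exc:
            trim_by_margin_lines(head, lat, None, PLANE, side_point=(10.0, 0.0, 0.0))
        assert "lateral" in str(exc.value)

    def test_facet_classification_matches_brute_force_vertex_test(self, unit_sphere):
        """Centroid classification agrees with an independent per-point test."""
        head = sphere_head(unit_sphere)
        lat = line3((0.2, 0.1), (0.3, -1.0))
        kept = trim_by_margin_lines(head, lat, None, PLANE, side_point=(-0.8, 0.0, 0.0))
        kept_set = set(int(k) for k in kept)
        centroids = head.mesh.triangles[head.head_facets].mean(axis=1)
        # independent sign test in the projection plane
        a = np.array([0.2, 0.1])
        d = np.array([0.3, -1.0]) / np.linalg.norm([0.3, -1.0])
        uv = centroids[:, [0, 2]] - a
        s = d[0] * uv[:, 1] - d[1] * uv[:, 0]
        sp = np.array([-0.8, 0.0]) - a
        want = np.sign(d[0] * sp[1] - d[1] * sp[0])
        agree = [
            (np.sign(s[i]) == want) == (int(f) in kept_set)
            for i, f in enumerate(head.head_facets)
        ]
        assert np.mean(agree) >= 0.995


class TestMirrorSymmetry:
    def test_mirrored_configuration_has_equal_area(self, unit_sphere):
        head = sphere_head(unit_sphere)
        lat = line3((0.3, 0.8), (-0.5, -1.0))
        med = line3((-0.7, 0.5), (-0.2, -1.0))
        kept = trim_by_margin_lines(head, lat, med, PLANE, side_point=(0.0, 0.0, 0.2))
        patch = apply_inferior_limit(kept, head, UP, limit_deg=30.0)

        mirrored = unit_sphere.copy()
        mirrored.vertices = mirrored.vertices * [-1.0, 1.0, 1.0]
        mirrored.invert()
        headm = sphere_head(mirrored)
        latm = line3((-0.3, 0.8), (0.5, -1.0))
        medm = line3((0.7, 0.5), (0.2, -1.0))
        keptm = trim_by_margin_lines(headm, latm, medm, PLANE, side_point=(0.0, 0.0, 0.2))
        patchm = apply_inferior_limit(keptm, headm, UP, limit_deg=30.0)
        assert patchm.area == pytest.approx(patch.area, rel=1e-9)


class TestPatchProperties:
    def test_patch_area_of_empty_set_is_zero(self, unit_sphere_coarse):
        patch = WeightBearingPatch(
            mesh=unit_sphere_coarse, facets=np.array([], dtype=int), boundary=[], area=0.0
        )
        assert patch_area(patch) == 0.0

    def test_patch_area_of_single_right_triangle(self):
        m = trimesh.Trimesh(
            vertices=[[0, 0, 0], [3, 0, 0], [0, 4, 0]], faces=[[0, 1, 2]], process=False
        )
        patch = WeightBearingPatch(mesh=m, facets=np.array([0]), boundary=[], area=6.0)
        assert patch_area(patch) == pytest.approx(6.0)

    def test_boundary_is_single_closed_loop_for_cap(self, unit_sphere_coarse):
        head = sphere_head(unit_sphere_coarse)
        patch = apply_inferior_limit(head.head_facets, head, UP, limit_deg=-30.0)
        assert len(patch.boundary) == 1
        loop = patch.boundary[0]
        assert len(loop) > 20
        # loop vertices sit near the 30-degree latitude
        lat = np.degrees(np.arcsin(loop[:, 2] / np.linalg.norm(loop, axis=1)))
        assert np.all(np.abs(lat - 30.0) < 5.0)

    def test_patch_is_subset_of_head_facets(self, unit_sphere_coarse):
        head = sphere_head(unit_sphere_coarse)
        patch = apply_inferior_limit(head.head_facets, head, UP, limit_deg=10.0)
        assert set(patch.facets.tolist()) <= set(head.head_facets.tolist())


class TestMonteCarloOracle:
    def test_oracle_matches_closed_form_zone(self):
        area = monte_carlo_patch_area(
            (0, 0, 0),
            1.0,
            [lambda p: elevation_mask(p, (0, 0, 0), UP, 30.0)],
            n=400_000,
            seed=3,
        )
        assert area == pytest.approx(3 * math.pi, rel=0.01)

    def test_oracle_matches_facet_area_on_composite_trim(self, unit_sphere):
        head = sphere_head(unit_sphere)
        lat = line3((0.4, 0.2), (-0.4, -1.0))
        med = line3((-0.6, 0.4), (-0.1, -1.0))
        side = (0.0, 0.0, 0.3)
        kept = trim_by_margin_lines(head, lat, med, PLANE, side_point=side)
        patch = apply_inferior_limit(kept, head, UP, limit_deg=30.0)
        ls = 1.0 if halfspace_mask(np.array([[0.0, 0.0, 0.3]]), lat, PLANE, 1.0)[0] else -1.0
        ms = 1.0 if halfspace_mask(np.array([[0.0, 0.0, 0.3]]), med, PLANE, 1.0)[0] else -1.0
        mc = monte_carlo_patch_area(
            head.center,
            head.radius,
            [
                lambda p: halfspace_mask(p, lat, PLANE, ls),
                lambda p: halfspace_mask(p, med, PLANE, ms),
                lambda p: elevation_mask(p, head.center, UP, 30.0),
            ],
            n=400_000,
            seed=9,
        )
        assert patch.area == pytest.approx(mc, rel=0.02)


class TestFillet:
    @pytest.fixture()
    def crescent_patch(self, unit_sphere):
        head = sphere_head(unit_sphere)
        lat = line3((0.2, 0.1), (0.4, -1.0))
        kept = trim_by_margin_lines(head, lat, None, PLANE, side_point=(-0.6, 0.0, 0.3))
        return apply_inferior_limit(kept, head, UP, limit_deg=20.0)

    def test_zero_radius_is_identity(self, crescent_patch):
        out = smooth_patch_boundary(crescent_patch, 0.0)
        assert out is crescent_patch

    def test_smoothing_never_adds_area(self, crescent_patch):
        out = smooth_patch_boundary(crescent_patch, 0.05)
        assert out.area <= crescent_patch.area

    def test_resmoothing_is_nearly_idempotent(self, crescent_patch):
        once = smooth_patch_boundary(crescent_patch, 0.05)
        twice = smooth_patch_boundary(once, 0.05)
        assert abs(twice.area - once.area) <= 0.001 * once.area

    def test_oversized_radius_returns_patch_unchanged(self, crescent_patch):
        out = smooth_patch_boundary(crescent_patch, 10.0)
        assert out.area == crescent_patch.area
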