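"""Parametric proximal-femur geometry with matched synthetic radiographs.

A stand-in for patient CT anatomy: the proximal femur is the union of a
spherical head, a cylindrical (capsule) neck and a capsule shaft whose
hemispherical top doubles as a greater-trochanter prominence.  The solid is
represented by a signed distance function (negative inside); the same SDF
drives

* surface extraction (marching cubes — watertight by construction),
* voxel-template tetrahedral meshing (5- or 6-tet cube templates),
* cortical/cancellous labeling (elements within ``cortical_thickness`` of
  the outer surface are cortical).

Coordinate frame: +x toward the patient's left (lateral for a left femur),
+y anterior (the AP projection direction), +z superior.  All lengths in mm.

Every generator is deterministic for a fixed seed and ships a
:class:`GroundTruth` record so downstream stages can be tested against known
answers without any scan data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .errors import MeshingError, ParameterError
from .fe_solver import CANCELLOUS, CORTICAL, TetModel
from .radiograph_geometry import RadiographLandmarkSet, lateral_sign
from .registration_projection import PlanarRegistration


@dataclass(frozen=True)
class FemurParams:
    """Parametric proximal-femur description (mm / degrees).

    Defaults are conventional adult dimensions (femoral head radius about
    24 mm, neck-shaft angle 130 deg); they are not derived from any specific
    subject.
    """

    head_radius: float = 24.0
    head_center: tuple = (0.0, 0.0, 0.0)
    neck_radius: float = 15.0
    neck_length: float = 38.0
    neck_shaft_angle: float = 130.0
    shaft_radius: float = 14.5
    shaft_length: float = 70.0
    cortical_thickness: float = 3.0
    blend_radius: float = 8.0
    side: str = "left"
    seed: int = 0

    def __post_init__(self):
        if not (self.head_radius > self.neck_radius > 0):
            raise ParameterError("require head_radius > neck_radius > 0")
        if not (0 < self.cortical_thickness < self.neck_radius):
            raise ParameterError("require 0 < cortical_thickness < neck_radius")
        if not (90.0 < self.neck_shaft_angle < 160.0):
            raise ParameterError("neck_shaft_angle must be in (90, 160) degrees")
        if self.shaft_radius <= 0 or self.shaft_length <= 0 or self.neck_length <= 0:
            raise ParameterError("all lengths must be positive")
        if self.blend_radius < 0:
            raise ParameterError("blend_radius must be non-negative")
        lateral_sign(self.side)  # validates

    @property
    def lat(self) -> float:
        return lateral_sign(self.side)

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.head_center, dtype=float)

    @property
    def neck_direction(self) -> np.ndarray:
        """Unit vector from the head center toward the neck-shaft junction."""
        a = math.radians(180.0 - self.neck_shaft_angle)
        return np.array([self.lat * math.sin(a), 0.0, -math.cos(a)])

    @property
    def junction(self) -> np.ndarray:
        """Neck-shaft junction point (center of the trochanteric cap)."""
        return self.center + self.neck_length * self.neck_direction

    @property
    def shaft_bottom(self) -> np.ndarray:
        return self.junction + np.array([0.0, 0.0, -self.shaft_length])

    @property
    def head_neck_junction_point(self) -> np.ndarray:
        """Where the neck axis pierces the head sphere (path endpoint)."""
        return self.center + self.head_radius * self.neck_direction


def _capsule_sdf(points: np.ndarray, a: np.ndarray, b: np.ndarray, r: float):
    ab = b - a
    t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1) - r


def _smooth_min(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth minimum; reduces to min for k = 0.

    Blends the two distance fields over a band of width ~k, rounding the
    reentrant crease where two primitives meet.
    """
    if k <= 0:
        return np.minimum(a, b)
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + h * (a - b) - k * h * (1.0 - h)


def femur_sdf(points, params: FemurParams) -> np.ndarray:
    """Signed distance to the femur solid (negative inside).

    The head sphere, neck capsule and shaft capsule are combined with a
    smooth union (``blend_radius``) so the head-neck and neck-shaft
    junctions carry an anatomical fillet rather than a sharp reentrant
    crease (which would act as an artificial stress concentrator in the FE
    stage).  Away from the junction bands the head surface is an exact
    sphere.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    d_head = np.linalg.norm(P - params.center, axis=1) - params.head_radius
    d_neck = _capsule_sdf(P, params.center, params.junction, params.neck_radius)
    d_shaft = _capsule_sdf(P, params.junction, params.shaft_bottom, params.shaft_radius)
    k = params.blend_radius
    return _smooth_min(d_head, _smooth_min(d_neck, d_shaft, k), k)


def head_region_predicate(params: FemurParams, margin: float | None = None):
    """Predicate selecting points on the *free* spherical part of the head.

    The smooth union only deforms the head sphere where the neck/shaft
    distance field drops below ``blend_radius``; points passing this
    predicate therefore lie on an exactly spherical portion of the surface.
    Used to give facet trimming and the Monte-Carlo area oracle an identical
    integration domain on synthetic anatomy.
    """
    m = params.blend_radius if margin is None else margin

    def pred(points):
        P = np.atleast_2d(np.asarray(points, dtype=float))
        d_neck = _capsule_sdf(P, params.center, params.junction, params.neck_radius)
        d_shaft = _capsule_sdf(P, params.junction, params.shaft_bottom, params.shaft_radius)
        return np.minimum(d_neck, d_shaft) >= m

    return pred


def head_cap_predicate(params: FemurParams, min_angle_deg: float = 75.0):
    """Predicate keeping points at a polar angle >= ``min_angle_deg`` from
    the neck axis (measured at the head center).

    A purely angular domain: insensitive to small radius/center errors of a
    fitted sphere, which makes it the right shared domain restriction when
    comparing facet-sum areas with spherical Monte-Carlo integrals on
    synthetic anatomy (the excluded cap covers the blended neck junction).
    """
    d = params.neck_direction
    cos_max = math.cos(math.radians(min_angle_deg))

    def pred(points):
        P = np.atleast_2d(np.asarray(points, dtype=float)) - params.center
        n = np.linalg.norm(P, axis=1)
        n = np.where(n < 1e-300, 1.0, n)
        return (P @ d) / n <= cos_max

    return pred


def femur_solid_volume(params: FemurParams, n: int = 400_000, seed: int = 1234) -> float:
    """Monte-Carlo volume of the union solid (mm^3), for meshing checks."""
    rng = np.random.default_rng(seed)
    lo, hi = _femur_bounds(params, margin=1.0)
    pts = rng.uniform(lo, hi, size=(n, 3))
    frac = float(np.mean(femur_sdf(pts, params) < 0))
    return frac * float(np.prod(hi - lo))


def _femur_bounds(params: FemurParams, margin: float):
    pts = np.array([params.center, params.junction, params.shaft_bottom])
    r = max(params.head_radius, params.shaft_radius, params.neck_radius)
    return pts.min(axis=0) - r - margin, pts.max(axis=0) + r + margin


@dataclass
class GroundTruth:
    """Exact generative quantities for testing downstream stages."""

    head_center: np.ndarray
    head_radius: float
    projection: PlanarRegistration
    landmarks: dict                      # name -> 3D point (y=0 for pelvis-side)
    head_vertex_mask: np.ndarray | None = None
    params: FemurParams | None = None

    def landmarks_2d(self) -> dict:
        """True-size AP projections (drop the anterior-posterior coordinate)."""
        return {k: np.array([v[0], v[2]]) for k, v in self.landmarks.items()}


def _femur_landmarks_3d(params: FemurParams) -> dict:
    c, r, lat = params.center, params.head_radius, params.lat
    J, rs = params.junction, params.shaft_radius
    return {
        "p1": np.array([J[0] + lat * rs, 0.0, J[2]]),   # greater trochanter, most lateral
        "p2": np.array([J[0], 0.0, J[2] + rs]),          # greater trochanter, top
        "p3": c + np.array([lat * r, 0.0, 0.0]),         # head, most lateral
        "p6": c + np.array([-lat * r, 0.0, 0.0]),        # head, most medial
        "p16": c + np.array([0.0, 0.0, r]),              # head, top
        "p19": c.copy(),                                 # head center
    }


def generate_femur_surface(
    params: FemurParams, pitch: float = 1.5
) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Triangulated femur surface via marching cubes on the SDF.

    Returns the watertight surface mesh and a ground-truth record whose
    ``head_vertex_mask`` tags vertices lying on the free spherical part of
    the head (away from the neck junction).
    """
    if pitch <= 0:
        raise ParameterError("pitch must be positive")
    lo, hi = _femur_bounds(params, margin=2.0 * pitch)
    shape = np.ceil((hi - lo) / pitch).astype(int) + 1
    axes = [lo[i] + pitch * np.arange(shape[i]) for i in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
    sdf = femur_sdf(grid.reshape(-1, 3), params).reshape(grid.shape[:3])
    verts, faces, _, _ = marching_cubes(sdf, level=0.0, spacing=(pitch,) * 3)
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True, validate=False)
    # head tag: on the sphere and clear of the neck/shaft primitives
    v = mesh.vertices
    on_sphere = np.abs(np.linalg.norm(v - params.center, axis=1) - params.head_radius)
    d_rest = np.minimum(
        _capsule_sdf(v, params.center, params.junction, params.neck_radius),
        _capsule_sdf(v, params.junction, params.shaft_bottom, params.shaft_radius),
    )
    mask = (on_sphere < 0.4 * pitch) & (d_rest > 0.25 * pitch)
    truth = GroundTruth(
        head_center=params.center,
        head_radius=params.head_radius,
        projection=PlanarRegistration.identity(),
        landmarks=_femur_landmarks_3d(params),
        head_vertex_mask=mask,
        params=params,
    )
    return mesh, truth


# ---------------------------------------------------------------------------
# voxel-template tetrahedral meshing
# ---------------------------------------------------------------------------

# cube corner offsets (i, j, k); corner index = standard binary ordering
_CUBE_CORNERS = np.array(
    [
        [0, 0, 0],  # 0
        [1, 0, 0],  # 1
        [1, 1, 0],  # 2
        [0, 1, 0],  # 3
        [0, 0, 1],  # 4
        [1, 0, 1],  # 5
        [1, 1, 1],  # 6
        [0, 1, 1],  # 7
    ]
)

# 6-tet (Kuhn) split around the 0-6 diagonal: conforming on all cubes.
_TEMPLATE_6 = [
    (0, 1, 2, 6),
    (0, 2, 3, 6),
    (0, 3, 7, 6),
    (0, 7, 4, 6),
    (0, 4, 5, 6),
    (0, 5, 1, 6),
]

# 5-tet split: four corner tets + one central; needs parity mirroring to
# conform across neighboring cubes.
_TEMPLATE_5 = [
    (0, 1, 2, 5),
    (0, 2, 3, 7),
    (0, 5, 7, 4),
    (2, 7, 5, 6),
    (0, 2, 7, 5),
]

# mirror map through x -> 1-x for odd-parity cubes
_MIRROR_X = {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4, 6: 7, 7: 6}


def _orient_template(template, corners=_CUBE_CORNERS):
    """Reorder each tet so its volume on the unit cube is positive."""
    out = []
    for tet in template:
        X = corners[list(tet)].astype(float)
        if np.linalg.det(X[1:] - X[0]) < 0:
            tet = (tet[0], tet[2], tet[1], tet[3])
        out.append(tet)
    return out


_TEMPLATE_6 = _orient_template(_TEMPLATE_6)
_TEMPLATE_5 = _orient_template(_TEMPLATE_5)
_TEMPLATE_5_MIRROR = _orient_template(
    [tuple(_MIRROR_X[i] for i in tet) for tet in _TEMPLATE_5]
)


def tets_from_voxels(
    voxel_ijk: np.ndarray, origin, voxel_size: float, template: str = "6"
) -> tuple[np.ndarray, np.ndarray]:
    """Lattice nodes and tetrahedra for a set of filled voxels.

    ``voxel_ijk``: (V, 3) integer voxel indices; node (i,j,k) sits at
    ``origin + voxel_size * (i,j,k)``.  Returns (nodes, elements).
    """
    if template not in ("5", "6"):
        raise ParameterError("template must be '5' or '6'")
    vox = np.asarray(voxel_ijk, dtype=np.int64)
    if vox.size == 0:
        raise MeshingError("no voxels inside the solid; voxel size too large?")
    corner_keys = vox[:, None, :] + _CUBE_CORNERS[None, :, :]  # (V, 8, 3)
    flat = corner_keys.reshape(-1, 3)
    uniq, inv = np.unique(flat, axis=0, return_inverse=True)
    corner_ids = inv.reshape(-1, 8)
    nodes = np.asarray(origin, dtype=float) + voxel_size * uniq
    if template == "6":
        tpl = np.array(_TEMPLATE_6)
        elements = corner_ids[:, tpl].reshape(-1, 4)
    else:
        parity = vox.sum(axis=1) % 2
        t_even = np.array(_TEMPLATE_5)
        t_odd = np.array(_TEMPLATE_5_MIRROR)
        parts = [
            corner_ids[parity == 0][:, t_even].reshape(-1, 4),
            corner_ids[parity == 1][:, t_odd].reshape(-1, 4),
        ]
        elements = np.vstack(parts)
    return nodes, elements


def generate_box_tet_mesh(
    lengths, voxel_size: float, template: str = "6", label: str = CORTICAL
) -> TetModel:
    """Axis-aligned box [0, L]^3-style mesh; handy for solver verification."""
    L = np.asarray(lengths, dtype=float).reshape(3)
    n = np.maximum(np.round(L / voxel_size).astype(int), 1)
    ijk = np.stack(
        np.meshgrid(*(np.arange(k) for k in n), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    nodes, elements = tets_from_voxels(ijk, np.zeros(3), voxel_size, template)
    return TetModel(
        nodes=nodes,
        elements=elements,
        labels=np.full(len(elements), label),
        element_type="tet4",
    )


def generate_tet_mesh(
    params: FemurParams, voxel_size: float = 3.0, template: str = "6"
) -> TetModel:
    """Voxel-template tetrahedral mesh of the femur solid.

    Interior voxels (SDF < 0 at the center) are split with the chosen cube
    template; elements are labeled cortical when their centroid lies within
    ``cortical_thickness`` of the outer surface, cancellous otherwise.
    """
    if voxel_size <= 0:
        raise ParameterError("voxel_size must be positive")
    if voxel_size > 2.0 * params.neck_radius:
        raise MeshingError(
            f"voxel_size {voxel_size} mm exceeds the neck diameter "
            f"{2 * params.neck_radius} mm"
        )
    lo, hi = _femur_bounds(params, margin=voxel_size)
    n = np.ceil((hi - lo) / voxel_size).astype(int)
    ijk = np.stack(
        np.meshgrid(*(np.arange(k) for k in n), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers = lo + voxel_size * (ijk + 0.5)
    inside = femur_sdf(centers, params) < 0
    nodes, elements = tets_from_voxels(ijk[inside], lo, voxel_size, template)
    centroids = nodes[elements].mean(axis=1)
    depth = femur_sdf(centroids, params)
    labels = np.where(depth > -params.cortical_thickness, CORTICAL, CANCELLOUS)
    return TetModel(
        nodes=nodes, elements=elements, labels=labels, element_type="tet4"
    )


# ---------------------------------------------------------------------------
# synthetic AP radiograph
# ---------------------------------------------------------------------------

#: Pelvis-side landmark offsets relative to the projected head center, in a
#: frame where +u is anatomically lateral and +v superior.  Entries are
#: (du, dv) in mm, except p4 which is placed exactly at the target CE angle.
#: r denotes the head radius.
def default_pelvis_offsets(r: float) -> dict:
    return {
        "p5": (-(r + 3.0) * math.sin(math.radians(35.0)),
               (r + 3.0) * math.cos(math.radians(35.0))),   # medial sourcil end
        "p7": (-(r + 4.0), -0.80 * r),                      # teardrop, inferior margin
        "p8": (-88.0, -14.0),                               # bilateral teardrop midpoint
        "p9": (-88.0, -30.0),                               # pubic symphysis center
        "p10": (-40.0, -75.0),                              # ischium, inferior margin
        "p11": (-0.30 * r, -0.95 * r),                      # post. acetab. / inf. head margin
        "p12": (30.0, 60.0),                                # ilium, most lateral
        "p13": (-20.0, 35.0),                               # ilium, inferior margin
        "p14": (-88.0, 95.0),                               # L5 center
        "p15": (5.0, 60.0),                                 # ilium inner margin near p12
        "p17": (-4.0, r + 3.0),                             # acetabular contour above p16
        "p18": (-(r + 2.0), -0.55 * r),                     # teardrop, lateral margin
    }


def generate_radiograph(
    truth: GroundTruth,
    magnification: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    target_ce_deg: float = 33.0,
    marker_true_diameter: float = 25.0,
    acetabular_rim_offset: float = 3.0,
    pelvis_offsets: dict | None = None,
) -> RadiographLandmarkSet:
    """Synthesize the 19-landmark AP radiograph of a generated femur.

    Femur-side landmarks are the vertical (drop-y) projections of the 3D
    ground truth; pelvis-side landmarks are placed from configurable offsets
    around the projected head center so that the center-edge angle equals
    ``target_ce_deg`` exactly when ``noise_sd`` is zero.  All points are then
    scaled by ``magnification`` about the image origin and jittered with
    isotropic Gaussian noise of standard deviation ``noise_sd`` (mm, film
    scale).  The marker measurement is ``magnification x true diameter``.
    """
    if magnification <= 0:
        raise ParameterError("magnification must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    params = truth.params
    if params is None:
        raise ParameterError("ground truth must carry the generating FemurParams")
    lat = params.lat
    r = truth.head_radius
    c2 = np.array([truth.head_center[0], truth.head_center[2]])
    pts = dict(truth.landmarks_2d())
    offsets = dict(default_pelvis_offsets(r))
    if pelvis_offsets:
        offsets.update(pelvis_offsets)
    for name, (du, dv) in offsets.items():
        pts[name] = c2 + np.array([lat * du, dv])
    ce = math.radians(target_ce_deg)
    r4 = r + acetabular_rim_offset
    pts["p4"] = c2 + np.array([lat * r4 * math.sin(ce), r4 * math.cos(ce)])
    rng = np.random.default_rng(seed)
    out = {}
    for name in sorted(pts):
        p = magnification * pts[name]
        if noise_sd > 0:
            p = p + rng.normal(0.0, noise_sd, size=2)
        out[name] = p
    # record the true radiograph transform (pure magnification about origin)
    truth.projection = PlanarRegistration(
        rotation_deg=0.0, translation=np.zeros(2), scale=magnification
    )
    return RadiographLandmarkSet(
        points=out,
        side=params.side,
        marker_measured_diameter=magnification * marker_true_diameter,
        marker_true_diameter=marker_true_diameter,
    )


def params_to_dict(params: FemurParams) -> dict:
    d = asdict(params)
    d["head_center"] = [float(v) for v in params.center]
    return d
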