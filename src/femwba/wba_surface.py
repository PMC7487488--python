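"""Trimming the femoral-head surface into the weight-bearing patch.

The quantified weight-bearing area ("surface gamma") is the subset of the
femoral-head surface satisfying three constraints:

1. on the patch side of the *lateral margin line* (4–M) extruded along the
   AP direction through the head,
2. on the patch side of the extruded *medial margin line* (5–W),
3. at elevation >= -limit_deg (default 30 deg) relative to the horizontal
   plane through the fitted head center, with "up" given by the outward
   joint-reaction-force axis.

Classification is facet-based (triangle centroids against the same
half-space / elevation predicates used by the Monte-Carlo oracle in
:func:`monte_carlo_patch_area`); mesh refinement controls the boundary
error, which the oracle bounds.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import EmptyPatchError, FitFailureError, ParameterError
from .registration_projection import DatumPlane, Line3D, project_to_plane

log = logging.getLogger(__name__)


@dataclass
class FemoralHeadModel:
    """A surface mesh with its fitted head sphere."""

    mesh: trimesh.Trimesh
    head_facets: np.ndarray      # facet indices on the spherical head region
    center: np.ndarray           # fitted center, mm
    radius: float                # fitted radius, mm
    fit_rms: float               # mm


def fit_head_sphere(
    mesh: trimesh.Trimesh,
    hint_point=None,
    hint_radius: float = 25.0,
    fit_band: float = 0.01,
    facet_band: float = 0.05,
    max_iter: int = 25,
    rms_threshold: float = 0.10,
) -> FemoralHeadModel:
    """Iterative least-squares sphere fit to the head region of a mesh.

    Starts from vertices within ``hint_radius`` of ``hint_point`` (default:
    the topmost vertex), fits an algebraic sphere, then re-selects vertices
    within a distance band of the current sphere until the selection is
    stable — first with a coarse band, then with the tight ``fit_band`` so
    vertices on the blended head-neck transition cannot bias center and
    radius.  ``head_facets`` are afterwards collected with the looser
    ``facet_band`` (both bands are fractions of the radius), keeping the
    near-spherical junction-adjacent surface available for trimming.

    Fails if the tight-selection rms exceeds ``rms_threshold * radius`` or
    the fitted radius is not commensurate with the mesh.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    if len(V) < 10:
        raise FitFailureError("mesh has too few vertices for a sphere fit")
    if hint_point is None:
        hint_point = V[np.argmax(V[:, 2])]
    hint_point = np.asarray(hint_point, dtype=float).reshape(3)
    sel = np.linalg.norm(V - hint_point, axis=1) < hint_radius
    if sel.sum() < 10:
        raise FitFailureError("sphere-fit hint region contains too few vertices")
    c, r = np.zeros(3), 0.0
    for band in (max(fit_band, 0.05), fit_band):
        for _ in range(max_iter):
            P = V[sel]
            A = np.column_stack([2.0 * P, np.ones(len(P))])
            b = (P**2).sum(axis=1)
            sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            c_new = sol[:3]
            r2 = sol[3] + c_new @ c_new
            if not np.isfinite(r2) or r2 <= 0:
                raise FitFailureError("sphere fit is degenerate")
            r_new = math.sqrt(r2)
            d = np.abs(np.linalg.norm(V - c_new, axis=1) - r_new)
            sel_new = d < band * r_new
            converged = np.array_equal(sel_new, sel) and np.allclose(
                c_new, c, atol=1e-12
            )
            c, r, sel = c_new, r_new, sel_new
            if sel.sum() < 10:
                raise FitFailureError("sphere-fit selection collapsed")
            if converged:
                break
    rms = float(np.sqrt(np.mean((np.linalg.norm(V[sel] - c, axis=1) - r) ** 2)))
    diag = float(np.linalg.norm(V.max(axis=0) - V.min(axis=0)))
    if rms > rms_threshold * r:
        raise FitFailureError(f"sphere-fit rms {rms:.3g} exceeds {rms_threshold:.0%} of radius")
    if r > 2.0 * diag:
        raise FitFailureError("fitted radius far exceeds the mesh extent; not a sphere")
    dv = np.abs(np.linalg.norm(V - c, axis=1) - r)
    on_sphere = dv < facet_band * r
    faces = np.asarray(mesh.faces)
    head_facets = np.flatnonzero(on_sphere[faces].all(axis=1))
    if head_facets.size == 0:
        raise FitFailureError("no facets lie on the fitted sphere")
    return FemoralHeadModel(
        mesh=mesh, head_facets=head_facets, center=c, radius=r, fit_rms=rms
    )


# ---------------------------------------------------------------------------
# classification predicates (shared by facet trimming and the MC oracle)
# ---------------------------------------------------------------------------

def halfspace_mask(
    points, line: Line3D, plane: DatumPlane, side_sign: float
) -> np.ndarray:
    """True where a 3D point lies on the ``side_sign`` side of the extruded line.

    The margin line lies in the datum plane; extruding it along the plane
    normal yields a plane whose signed side (in in-plane coordinates) is the
    cross product of the line direction with anchor->point.
    """
    if side_sign == 0:
        raise ParameterError("side_sign must be +1 or -1")
    uv = project_to_plane(points, plane)
    a = project_to_plane(line.point, plane)[0]
    d3 = project_to_plane(
        [line.point, line.point + line.direction], plane
    )
    d = d3[1] - d3[0]
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise ParameterError("margin line is parallel to the plane normal")
    d = d / n
    s = d[0] * (uv[:, 1] - a[1]) - d[1] * (uv[:, 0] - a[0])
    return np.sign(s) == np.sign(side_sign)


def elevation_mask(
    points, center, up_direction, limit_deg: float
) -> np.ndarray:
    """True where elevation above the horizontal plane through ``center`` is
    >= ``-limit_deg``; ``up_direction`` is the outward JRF axis (superior)."""
    u = np.asarray(up_direction, dtype=float).reshape(3)
    nu = np.linalg.norm(u)
    if abs(nu - 1.0) > 1e-6:
        raise ParameterError("up_direction must be a unit vector")
    w = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(center, float)
    nw = np.linalg.norm(w, axis=1)
    nw = np.where(nw < 1e-300, 1.0, nw)
    elev = np.degrees(np.arcsin(np.clip((w @ u) / nw, -1.0, 1.0)))
    return elev >= -limit_deg


def trim_by_margin_lines(
    head: FemoralHeadModel,
    lateral_line: Line3D | None,
    medial_line: Line3D | None,
    plane: DatumPlane,
    side_point=None,
    lateral_side_sign: float | None = None,
    medial_side_sign: float | None = None,
    facets=None,
) -> np.ndarray:
    """Keep head facets on the patch side of both extruded margin lines.

    The patch side of each line is the side containing ``side_point``
    (default: the fitted head center), unless explicit signs are given.
    Either line may be None (no trim).  Returns facet indices ("surface
    beta").
    """
    facets = np.asarray(head.head_facets if facets is None else facets, dtype=np.int64)
    if facets.size == 0:
        raise EmptyPatchError("input facet set")
    tri = head.mesh.triangles[facets]
    centroids = tri.mean(axis=1)
    ref = np.asarray(head.center if side_point is None else side_point, float).reshape(3)
    keep = np.ones(len(facets), dtype=bool)
    for name, line, sign in (
        ("lateral margin (4-M)", lateral_line, lateral_side_sign),
        ("medial margin (5-W)", medial_line, medial_side_sign),
    ):
        if line is None:
            continue
        if sign is None:
            ref_mask = halfspace_mask(ref[None, :], line, plane, 1.0)[0]
            sign = 1.0 if ref_mask else -1.0
        kept = halfspace_mask(centroids, line, plane, sign)
        removed = int(keep.sum() - (keep & kept).sum())
        log.info("%s removed %d facets", name, removed)
        keep &= kept
        if not keep.any():
            raise EmptyPatchError(name)
    return facets[keep]


@dataclass
class WeightBearingPatch:
    """Facet subset of the head surface forming the weight-bearing area."""

    mesh: trimesh.Trimesh
    facets: np.ndarray               # indices into mesh.faces
    boundary: list                   # list of (K, 3) ordered loop points
    area: float                      # mm^2
    provenance: dict = field(default_factory=dict)

    def facet_areas(self) -> np.ndarray:
        return self.mesh.area_faces[self.facets]

    def centroid(self) -> np.ndarray:
        """Area-weighted centroid of the patch facets."""
        a = self.facet_areas()
        c = self.mesh.triangles[self.facets].mean(axis=1)
        return (a[:, None] * c).sum(axis=0) / a.sum()

    def submesh(self) -> trimesh.Trimesh:
        return self.mesh.submesh([self.facets], append=True)


def _facet_adjacency_components(mesh: trimesh.Trimesh, facets: np.ndarray):
    """Edge-connected components of a facet subset (list of index arrays)."""
    fset = {int(f): i for i, f in enumerate(facets)}
    parent = list(range(len(facets)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for fa, fb in mesh.face_adjacency:
        ia, ib = fset.get(int(fa)), fset.get(int(fb))
        if ia is not None and ib is not None:
            ra, rb = find(ia), find(ib)
            if ra != rb:
                parent[ra] = rb
    groups: dict[int, list] = {}
    for i in range(len(facets)):
        groups.setdefault(find(i), []).append(i)
    return [facets[np.array(g)] for g in groups.values()]


def _boundary_loops(mesh: trimesh.Trimesh, facets: np.ndarray) -> list:
    """Ordered boundary polylines of a facet subset."""
    faces = np.asarray(mesh.faces)[facets]
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    bnd = uniq[counts == 1]
    if len(bnd) == 0:
        return []
    nxt: dict[int, list] = {}
    for a, b in bnd:
        nxt.setdefault(int(a), []).append(int(b))
        nxt.setdefault(int(b), []).append(int(a))
    unused = {tuple(e) for e in bnd}
    loops = []
    while unused:
        a0, b0 = next(iter(unused))
        unused.discard((a0, b0))
        loop = [a0, b0]
        while True:
            cur, prev = loop[-1], loop[-2]
            cands = [v for v in nxt.get(cur, []) if v != prev
                     and (tuple(sorted((cur, v))) in unused)]
            if not cands:
                break
            v = cands[0]
            unused.discard(tuple(sorted((cur, v))))
            if v == loop[0]:
                break
            loop.append(v)
        loops.append(np.asarray(mesh.vertices)[np.array(loop)])
    loops.sort(key=len, reverse=True)
    return loops


def apply_inferior_limit(
    facets,
    head: FemoralHeadModel,
    jrf_direction=(0.0, 0.0, 1.0),
    limit_deg: float = 30.0,
    keep_largest_component: bool = True,
    provenance: dict | None = None,
) -> WeightBearingPatch:
    """Trim "surface beta" by the inferior elevation limit ("surface gamma").

    Keeps facets whose centroid elevation relative to the horizontal plane
    through the fitted center is >= ``-limit_deg``, the superior sense given
    by the outward ``jrf_direction``; assembles the boundary polyline and the
    summed facet area.
    """
    facets = np.asarray(facets, dtype=np.int64)
    if facets.size == 0:
        raise EmptyPatchError("input facet set")
    u = np.asarray(jrf_direction, dtype=float).reshape(3)
    u = u / np.linalg.norm(u)
    centroids = head.mesh.triangles[facets].mean(axis=1)
    kept = elevation_mask(centroids, head.center, u, limit_deg)
    log.info("inferior limit (%g deg) removed %d facets", limit_deg,
             int(len(facets) - kept.sum()))
    if not kept.any():
        raise EmptyPatchError(f"inferior limit ({limit_deg} deg)")
    sub = facets[kept]
    n_components = 1
    if keep_largest_component:
        comps = _facet_adjacency_components(head.mesh, sub)
        n_components = len(comps)
        if n_components > 1:
            comps.sort(key=lambda c: head.mesh.area_faces[c].sum(), reverse=True)
            log.warning("patch has %d components; keeping the largest", n_components)
            sub = comps[0]
    area = float(head.mesh.area_faces[sub].sum())
    prov = dict(provenance or {})
    prov.update(
        {
            "limit_deg": float(limit_deg),
            "jrf_up_direction": [float(v) for v in u],
            "n_components_before_selection": n_components,
            "fitted_center_mm": [float(v) for v in head.center],
            "fitted_radius_mm": float(head.radius),
        }
    )
    return WeightBearingPatch(
        mesh=head.mesh,
        facets=sub,
        boundary=_boundary_loops(head.mesh, sub),
        area=area,
        provenance=prov,
    )


def patch_area(patch: WeightBearingPatch) -> float:
    """Exact sum of the patch facet areas, mm^2."""
    if len(patch.facets) == 0:
        return 0.0
    return float(patch.mesh.area_faces[patch.facets].sum())


def monte_carlo_patch_area(
    center,
    radius: float,
    predicates,
    n: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Independent spherical-surface-integral oracle for the patch area.

    Samples ``n`` points uniformly on the sphere and applies the same
    classification predicates used for facet trimming; returns
    ``4 pi r^2 * kept fraction`` (mm^2).  ``predicates`` is an iterable of
    callables mapping (N, 3) points to boolean masks.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(int(n), 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = np.asarray(center, dtype=float) + radius * v
    keep = np.ones(len(pts), dtype=bool)
    for pred in predicates:
        keep &= np.asarray(pred(pts), dtype=bool)
    return 4.0 * math.pi * radius**2 * float(np.mean(keep))


def smooth_patch_boundary(
    patch: WeightBearingPatch, fillet_radius: float = 1.0
) -> WeightBearingPatch:
    """Round convex boundary corners with arcs of the given radius.

    Each convex corner (one whose chord shortcut stays inside the patch) is
    replaced by two points trimmed back along the adjacent edges by
    ``fillet_radius * tan(theta/2)`` (clamped to 45% of either edge); facets
    whose centroid falls in a cut corner triangle are dropped and the area is
    recomputed.  Concave corners are left untouched, so smoothing never adds
    area.  A fillet radius too large for the patch returns it unchanged with
    a warning.
    """
    if fillet_radius < 0:
        raise ParameterError("fillet_radius must be non-negative")
    if fillet_radius == 0 or not patch.boundary:
        return patch
    inradius_proxy = math.sqrt(max(patch.area, 0.0) / math.pi)
    if fillet_radius > 0.5 * inradius_proxy:
        log.warning(
            "fillet radius %.2f mm too large for patch (~%.2f mm); skipping",
            fillet_radius, inradius_proxy,
        )
        return patch
    loop = np.asarray(patch.boundary[0], dtype=float)
    K = len(loop)
    if K < 4:
        return patch
    centroids = patch.mesh.triangles[patch.facets].mean(axis=1)
    drop = np.zeros(len(patch.facets), dtype=bool)
    new_loop = []
    cut_triangles = []
    for i in range(K):
        p_prev, p, p_next = loop[i - 1], loop[i], loop[(i + 1) % K]
        e1, e2 = p - p_prev, p_next - p
        n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
        if n1 < 1e-12 or n2 < 1e-12:
            continue
        cosang = np.clip((e1 @ e2) / (n1 * n2), -1.0, 1.0)
        theta = math.acos(cosang)  # turning angle
        if theta < 1e-3:
            new_loop.append(p)
            continue
        t = min(fillet_radius * math.tan(theta / 2.0), 0.45 * n1, 0.45 * n2)
        a = p - (t / n1) * e1
        b = p + (t / n2) * e2
        cut_triangles.append((a, p, b))
        new_loop.extend([a, b])
    # drop facets whose centroid lies inside a cut corner triangle
    for a, p, b in cut_triangles:
        e1 = p - a
        e2 = b - a
        nrm = np.cross(e1, e2)
        n2v = nrm @ nrm
        if n2v < 1e-18:
            continue
        w = centroids - a
        d00, d01, d11 = e1 @ e1, e1 @ e2, e2 @ e2
        d20 = w @ e1
        d21 = w @ e2
        denom = d00 * d11 - d01 * d01
        if abs(denom) < 1e-18:
            continue
        v_ = (d11 * d20 - d01 * d21) / denom
        w_ = (d00 * d21 - d01 * d20) / denom
        inside = (v_ >= -1e-9) & (w_ >= -1e-9) & (v_ + w_ <= 1 + 1e-9)
        # stay local: only near the corner plane
        dist = np.abs(w @ (nrm / math.sqrt(n2v)))
        drop |= inside & (dist < 2.0 * fillet_radius)
    kept = patch.facets[~drop]
    if kept.size == 0:
        log.warning("filleting would remove every facet; returning unsmoothed patch")
        return patch
    area = float(patch.mesh.area_faces[kept].sum())
    prov = dict(patch.provenance)
    prov["fillet_radius_mm"] = float(fillet_radius)
    prov["fillet_area_change_mm2"] = float(area - patch.area)
    return WeightBearingPatch(
        mesh=patch.mesh,
        facets=kept,
        boundary=[np.asarray(new_loop)] + patch.boundary[1:],
        area=area,
        provenance=prov,
    )
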