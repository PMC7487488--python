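"""Small-strain linear-elastic tetrahedral finite elements.

Supports 4-node (constant-strain) and 10-node (quadratic, straight-edged)
tetrahedra with bi-material isotropic elasticity, Dirichlet constraints,
sparse direct solution, and stress postprocessing (von Mises, sorted
principal stresses, arc-length stress paths).

Units are fixed as N — mm — MPa throughout.

The three hip loading cases compared by :func:`compare_load_cases` are

* **A** — joint reaction force distributed over the quantified weight-bearing
  patch (tributary-area nodal weights),
* **B** — the same force over a circular region (default diameter 20 mm) at
  the top of the femoral head,
* **C** — the full force at the single apical node.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from .errors import MeshingError, ParameterError, SolverError

CORTICAL = "cortical"
CANCELLOUS = "cancellous"

# Abaqus C3D10 midside edges: node 5 on 1-2, 6 on 2-3, 7 on 3-1, 8 on 1-4,
# 9 on 2-4, 10 on 3-4 (zero-based pairs below).
TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))

_TET_FACES = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))


@dataclass
class TetModel:
    """Labeled tetrahedral mesh with named node sets."""

    nodes: np.ndarray          # (N, 3) float, mm
    elements: np.ndarray       # (M, 4) or (M, 10) int
    labels: np.ndarray         # (M,) str-like, e.g. "cortical"/"cancellous"
    node_sets: dict = field(default_factory=dict)
    element_type: str = "tet4"

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        n_per = {"tet4": 4, "tet10": 10}.get(self.element_type)
        if n_per is None:
            raise ParameterError(f"unknown element type {self.element_type!r}")
        if self.elements.ndim != 2 or self.elements.shape[1] != n_per:
            raise MeshingError(
                f"{self.element_type} elements must be (M, {n_per}), "
                f"got {self.elements.shape}"
            )
        if len(self.labels) != len(self.elements):
            raise MeshingError("one material label per element required")
        if self.elements.size and (
            self.elements.min() < 0 or self.elements.max() >= len(self.nodes)
        ):
            raise MeshingError("element connectivity references invalid nodes")
        for name, ids in self.node_sets.items():
            ids = np.asarray(ids, dtype=np.int64)
            if ids.size and (ids.min() < 0 or ids.max() >= len(self.nodes)):
                raise MeshingError(f"node set {name!r} references invalid nodes")
            self.node_sets[name] = ids

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def corner_elements(self) -> np.ndarray:
        return self.elements[:, :4]

    def element_volumes(self) -> np.ndarray:
        X = self.nodes[self.corner_elements()]
        d = X[:, 1:] - X[:, :1]
        return np.linalg.det(d) / 6.0

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.corner_elements()].mean(axis=1)

    def boundary_faces(self) -> np.ndarray:
        """Triangular faces owned by exactly one element (corner nodes)."""
        faces, _ = self._boundary_faces_with_owner()
        return faces

    def _boundary_faces_with_owner(self):
        tets = self.corner_elements()
        M = len(tets)
        faces = np.concatenate([tets[:, f] for f in _TET_FACES])
        key = np.sort(faces, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
        bidx = idx[counts == 1]
        return faces[bidx], bidx

    def boundary_nodes(self) -> np.ndarray:
        """All nodes on the outer surface (midside nodes included for tet10)."""
        faces, bidx = self._boundary_faces_with_owner()
        nodes = [np.unique(faces)]
        if self.element_type == "tet10":
            # local midside indices belonging to each local corner face
            face_mids = {0: (4, 5, 6), 1: (4, 8, 7), 2: (6, 9, 7), 3: (5, 9, 8)}
            elem = bidx % len(self.elements)
            floc = bidx // len(self.elements)
            for f, mids in face_mids.items():
                sel = elem[floc == f]
                if sel.size:
                    nodes.append(np.unique(self.elements[sel][:, mids]))
        return np.unique(np.concatenate(nodes))


@dataclass
class MaterialSpec:
    """Per-label isotropic elastic constants (E in MPa, Poisson ratio nu).

    The defaults are conventional literature values for adult femoral
    cortical and cancellous bone; they are configuration inputs, not
    reference results.
    """

    materials: dict = field(
        default_factory=lambda: {
            CORTICAL: (16800.0, 0.3),
            CANCELLOUS: (840.0, 0.2),
        }
    )

    def __post_init__(self):
        for label, (E, nu) in self.materials.items():
            if E <= 0:
                raise ParameterError(f"E must be positive for {label!r}")
            if not (-1.0 < nu < 0.5):
                raise ParameterError(f"nu must be in (-1, 0.5) for {label!r}")

    def d_matrix(self, label) -> np.ndarray:
        E, nu = self.materials[str(label)]
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] = lam + 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


# 4-point Gauss rule on the reference tetrahedron (degree 2).
_GA, _GB = 0.5854101966249685, 0.1381966011250105
_GAUSS4 = np.array(
    [
        [_GA, _GB, _GB],
        [_GB, _GA, _GB],
        [_GB, _GB, _GA],
        [_GB, _GB, _GB],
    ]
)


def _tet10_dshape(xi) -> np.ndarray:
    """(10, 3) reference-coordinate shape-function gradients at point xi."""
    x, y, z = xi
    L = np.array([1.0 - x - y - z, x, y, z])
    dL = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    dN = np.zeros((10, 3))
    for i in range(4):
        dN[i] = (4 * L[i] - 1) * dL[i]
    for m, (a, b) in enumerate(TET10_EDGES):
        dN[4 + m] = 4 * (L[a] * dL[b] + L[b] * dL[a])
    return dN


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrices from nodal gradients.

    grads: (M, n, 3) spatial shape-function gradients -> B: (M, 6, 3n) with
    engineering shear strain ordering (xx, yy, zz, xy, yz, zx).
    """
    M, n, _ = grads.shape
    B = np.zeros((M, 6, 3 * n))
    gx, gy, gz = grads[:, :, 0], grads[:, :, 1], grads[:, :, 2]
    idx = np.arange(n)
    B[:, 0, 3 * idx] = gx
    B[:, 1, 3 * idx + 1] = gy
    B[:, 2, 3 * idx + 2] = gz
    B[:, 3, 3 * idx] = gy
    B[:, 3, 3 * idx + 1] = gx
    B[:, 4, 3 * idx + 1] = gz
    B[:, 4, 3 * idx + 2] = gy
    B[:, 5, 3 * idx] = gz
    B[:, 5, 3 * idx + 2] = gx
    return B


def _element_jacobians(model: TetModel):
    """Constant affine Jacobians (valid for straight-edged tet4/tet10)."""
    X = model.nodes[model.corner_elements()]
    J = (X[:, 1:] - X[:, :1]).transpose(0, 2, 1)  # dx/dxi, (M, 3, 3)
    detJ = np.linalg.det(J)
    if detJ.size and detJ.min() <= 0:
        bad = int(np.argmin(detJ))
        raise SolverError(
            f"element {bad} has non-positive Jacobian ({detJ.min():.3e}); "
            "inverted or degenerate tetrahedron"
        )
    return J, detJ


def _centroid_grads(model: TetModel, J, detJ) -> np.ndarray:
    """Spatial shape-function gradients at the element centroid, (M, n, 3)."""
    Jinv = np.linalg.inv(J)
    if model.element_type == "tet4":
        dN = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        return np.einsum("nj,ejk->enk", dN, Jinv)
    dN = _tet10_dshape(np.full(3, 0.25))
    return np.einsum("nj,ejk->enk", dN, Jinv)


def assemble_stiffness(model: TetModel, materials: MaterialSpec) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (3N x 3N, CSR)."""
    J, detJ = _element_jacobians(model)
    Jinv = np.linalg.inv(J)
    n_per = model.elements.shape[1]
    ndof_e = 3 * n_per
    M = model.n_elements
    Ke = np.zeros((M, ndof_e, ndof_e))
    labels = np.asarray(model.labels).astype(str)
    for label in np.unique(labels):
        sel = np.flatnonzero(labels == label)
        D = materials.d_matrix(label)
        Ji = Jinv[sel]
        dJ = detJ[sel]
        if model.element_type == "tet4":
            dN = np.array([[-1.0, -1.0, -1.0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
            grads = np.einsum("nj,ejk->enk", dN, Ji)
            B = _b_matrix(grads)
            Ke[sel] = np.einsum(
                "eia,ij,ejb->eab", B, D, B, optimize=True
            ) * (dJ / 6.0)[:, None, None]
        else:
            acc = np.zeros((len(sel), ndof_e, ndof_e))
            for xi in _GAUSS4:
                dN = _tet10_dshape(xi)
                grads = np.einsum("nj,ejk->enk", dN, Ji)
                B = _b_matrix(grads)
                acc += np.einsum("eia,ij,ejb->eab", B, D, B, optimize=True)
            Ke[sel] = acc * (dJ / 24.0)[:, None, None]
    edof = (3 * model.elements[:, :, None] + np.arange(3)).reshape(M, ndof_e)
    rows = np.repeat(edof, ndof_e, axis=1).ravel()
    cols = np.tile(edof, (1, ndof_e)).ravel()
    K = sp.coo_matrix(
        (Ke.ravel(), (rows.astype(np.int32), cols.astype(np.int32))),
        shape=(3 * model.n_nodes, 3 * model.n_nodes),
    ).tocsr()
    return K


def node_dofs(nodes) -> np.ndarray:
    n = np.asarray(nodes, dtype=np.int64).reshape(-1)
    return (3 * n[:, None] + np.arange(3)).ravel()


def solve_displacements(
    K: sp.csr_matrix,
    f: np.ndarray,
    fixed_nodes,
    fixed_values: np.ndarray | None = None,
    lu=None,
):
    """Solve K u = f with prescribed displacements on ``fixed_nodes``.

    Returns (u, reactions, lu); ``lu`` is the sparse LU factorization of the
    free-free block and can be passed back in to reuse it across load cases.
    ``reactions`` is a full-length vector, nonzero only at constrained dofs.
    """
    fixed_nodes = np.asarray(fixed_nodes, dtype=np.int64).reshape(-1)
    if fixed_nodes.size == 0:
        raise SolverError("no constrained nodes; system has rigid-body modes")
    ndof = K.shape[0]
    fdof = node_dofs(fixed_nodes)
    uc = np.zeros(len(fdof))
    if fixed_values is not None:
        uc = np.asarray(fixed_values, dtype=float).reshape(len(fdof))
    free = np.setdiff1d(np.arange(ndof), fdof, assume_unique=False)
    if lu is None:
        Kff = K[free][:, free].tocsc()
        try:
            # symmetric-mode ordering: large speedup for SPD elasticity matrices
            lu = spla.splu(
                Kff, permc_spec="MMD_AT_PLUS_A", options=dict(SymmetricMode=True)
            )
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"singular stiffness matrix: {exc}") from exc
    rhs = f[free] - K[free][:, fdof] @ uc
    u = np.zeros(ndof)
    u[free] = lu.solve(rhs)
    u[fdof] = uc
    if not np.all(np.isfinite(u)):
        raise SolverError("solver produced non-finite displacements")
    reactions = np.zeros(ndof)
    reactions[fdof] = (K[fdof] @ u) - f[fdof]
    return u, reactions, lu


def compute_stress(model: TetModel, materials: MaterialSpec, u: np.ndarray):
    """Element-centroid stress tensors (6 components), from displacements."""
    J, detJ = _element_jacobians(model)
    grads = _centroid_grads(model, J, detJ)
    B = _b_matrix(grads)
    edof = (3 * model.elements[:, :, None] + np.arange(3)).reshape(
        model.n_elements, -1
    )
    ue = u[edof]
    strain = np.einsum("eij,ej->ei", B, ue)
    stress = np.zeros_like(strain)
    labels = np.asarray(model.labels).astype(str)
    for label in np.unique(labels):
        sel = labels == label
        stress[sel] = strain[sel] @ materials.d_matrix(label).T
    return stress, strain


def von_mises(stress6) -> np.ndarray:
    """Von Mises equivalent stress from (..., 6) tensors (xx,yy,zz,xy,yz,zx)."""
    s = np.atleast_2d(np.asarray(stress6, dtype=float))
    sx, sy, sz, txy, tyz, tzx = (s[:, i] for i in range(6))
    vm = np.sqrt(
        0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
        + 3.0 * (txy**2 + tyz**2 + tzx**2)
    )
    return vm if np.asarray(stress6).ndim > 1 else vm[0]


def principal_stresses(stress6) -> np.ndarray:
    """Sorted (descending) principal stresses from (..., 6) tensors."""
    s = np.atleast_2d(np.asarray(stress6, dtype=float))
    T = np.zeros((len(s), 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = s[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = s[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = s[:, 5]
    vals = np.linalg.eigvalsh(T)[:, ::-1]
    return vals if np.asarray(stress6).ndim > 1 else vals[0]


@dataclass
class StressField:
    """Solution of one load case."""

    displacements: np.ndarray   # (N, 3) mm
    stress: np.ndarray          # (M, 6) MPa
    von_mises: np.ndarray       # (M,) MPa
    principal: np.ndarray       # (M, 3) MPa, descending
    reactions: np.ndarray       # (3N,) N, nonzero at fixed dofs
    applied: np.ndarray         # (3N,) N
    strain_energy: float        # N*mm

    def reaction_resultant(self) -> np.ndarray:
        return self.reactions.reshape(-1, 3).sum(axis=0)

    def applied_resultant(self) -> np.ndarray:
        return self.applied.reshape(-1, 3).sum(axis=0)

    def equilibrium_residual(self) -> float:
        """|sum reactions + sum applied| / |sum applied|."""
        a = self.applied_resultant()
        return float(
            np.linalg.norm(self.reaction_resultant() + a)
            / max(np.linalg.norm(a), 1e-300)
        )


@dataclass
class LoadCase:
    """A resolved nodal force distribution for one loading condition.

    ``coupling`` selects how the region carries the force: "distributed"
    applies the tributary-area nodal forces as-is, "kinematic" additionally
    ties the region's nodes to a common translation (a rigid, non-rotating
    coupling surface, as commercial solvers realize surface loads via
    coupling constraints).
    """

    kind: str                      # "A_patch" | "B_circle" | "C_point"
    total_force: np.ndarray        # (3,) N
    node_ids: np.ndarray           # (K,) loaded nodes
    weights: np.ndarray            # (K,) summing to 1
    extra_loads: tuple = ()        # ((node_id, force3), ...)
    coupling: str = "distributed"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.total_force = np.asarray(self.total_force, dtype=float).reshape(3)
        self.node_ids = np.asarray(self.node_ids, dtype=np.int64).reshape(-1)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.node_ids) != len(self.weights):
            raise ParameterError("one weight per loaded node required")

    def force_vector(self, n_nodes: int) -> np.ndarray:
        f = np.zeros(3 * n_nodes)
        for i, w in zip(self.node_ids, self.weights):
            f[3 * i : 3 * i + 3] += w * self.total_force
        for node, force in self.extra_loads:
            f[3 * node : 3 * node + 3] += np.asarray(force, dtype=float)
        return f


def tributary_weights(model: TetModel, region_nodes) -> np.ndarray:
    """Area-consistent nodal weights over a boundary region (sum to 1).

    Each boundary triangle whose three corners lie in the region contributes
    one third of its area to each corner; faces partially inside contribute to
    their member nodes only.  Falls back to uniform weights for regions too
    small to own a face.
    """
    region = np.asarray(region_nodes, dtype=np.int64).reshape(-1)
    if region.size == 0:
        raise ParameterError("empty load region")
    inset = np.zeros(model.n_nodes, dtype=bool)
    inset[region] = True
    faces = model.boundary_faces()
    w = np.zeros(model.n_nodes)
    member = inset[faces]
    full = member.all(axis=1)
    # prefer faces fully inside the region (the consistent nodal load for a
    # uniform traction); fall back to partially covered faces for regions too
    # small to own a face, then to uniform weights
    use = full if full.any() else member.any(axis=1)
    if use.any():
        tri = model.nodes[faces[use]]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        for k in range(3):
            sel = member[use][:, k]
            np.add.at(w, faces[use][:, k][sel], areas[sel] / 3.0)
        w[~inset] = 0.0
    if w[region].sum() <= 0:
        w[region] = 1.0
    out = w[region]
    return out / out.sum()


def build_load_case(
    model: TetModel,
    kind: str,
    total_force,
    *,
    patch_nodes=None,
    circle_center=None,
    circle_diameter: float = 20.0,
    apex_node: int | None = None,
    candidate_nodes=None,
    extra_loads=(),
    coupling: str = "distributed",
) -> LoadCase:
    """Resolve a loading condition into nodal forces.

    A: tributary-area weights over ``patch_nodes``.
    B: tributary-area weights over boundary nodes within ``circle_diameter/2``
       of ``circle_center`` (Euclidean, among ``candidate_nodes`` or all
       boundary nodes).
    C: full force at ``apex_node``.
    """
    F = np.asarray(total_force, dtype=float).reshape(3)
    if np.linalg.norm(F) <= 0:
        raise ParameterError("total force must be nonzero")
    meta = {"distribution": "tributary-area nodal forces"}
    if kind == "A_patch":
        if patch_nodes is None or len(patch_nodes) == 0:
            raise ParameterError("case A requires a nonempty patch node set")
        ids = np.asarray(patch_nodes, dtype=np.int64)
        w = tributary_weights(model, ids)
    elif kind == "B_circle":
        if circle_center is None:
            raise ParameterError("case B requires a circle center")
        cand = (
            np.asarray(candidate_nodes, dtype=np.int64)
            if candidate_nodes is not None
            else model.boundary_nodes()
        )
        c = np.asarray(circle_center, dtype=float).reshape(3)
        d = np.linalg.norm(model.nodes[cand] - c, axis=1)
        ids = cand[d <= circle_diameter / 2.0]
        if ids.size == 0:
            raise ParameterError(
                f"no boundary nodes within {circle_diameter / 2:.1f} mm of the circle center"
            )
        w = tributary_weights(model, ids)
        meta["circle_center"] = [float(v) for v in c]
        meta["circle_diameter_mm"] = float(circle_diameter)
    elif kind == "C_point":
        if apex_node is None:
            raise ParameterError("case C requires an apex node")
        ids = np.array([int(apex_node)], dtype=np.int64)
        w = np.array([1.0])
        meta["distribution"] = "single-node point load"
    else:
        raise ParameterError(f"unknown load case kind {kind!r}")
    if coupling not in ("distributed", "kinematic"):
        raise ParameterError(f"unknown coupling {coupling!r}")
    if coupling == "kinematic" and kind != "C_point":
        meta["distribution"] = "kinematic coupling (rigid non-rotating surface)"
    else:
        coupling = "distributed"
    meta["coupling"] = coupling
    return LoadCase(
        kind=kind,
        total_force=F,
        node_ids=ids,
        weights=w,
        extra_loads=tuple((int(n), np.asarray(f, float).reshape(3)) for n, f in extra_loads),
        coupling=coupling,
        metadata=meta,
    )


def _solve_kinematic_coupling(K, f, region_nodes, fixed_nodes):
    """Solve with the region's nodes tied to one common translation.

    The cluster is condensed onto a master translation via a prolongation
    matrix T (u = T u_red); forces applied inside the region accumulate on
    the master, so the resultant is preserved exactly.
    """
    N = K.shape[0] // 3
    region = np.asarray(region_nodes, dtype=np.int64).reshape(-1)
    fixed = np.asarray(fixed_nodes, dtype=np.int64).reshape(-1)
    if np.intersect1d(region, fixed).size:
        raise SolverError("coupled load region overlaps the fixed node set")
    newid = np.full(N, -1, dtype=np.int64)
    keepers = np.setdiff1d(np.arange(N), region)
    newid[keepers] = np.arange(len(keepers))
    m_red = len(keepers)
    tgt = np.where(newid >= 0, newid, m_red)
    cols = (3 * tgt[:, None] + np.arange(3)).ravel()
    T = sp.coo_matrix(
        (np.ones(3 * N), (np.arange(3 * N), cols)), shape=(3 * N, 3 * (m_red + 1))
    ).tocsr()
    Kr = (T.T @ K @ T).tocsr()
    ur, _, _ = solve_displacements(Kr, T.T @ f, newid[fixed])
    u = T @ ur
    fdof = node_dofs(fixed)
    reactions = np.zeros(3 * N)
    reactions[fdof] = (K[fdof] @ u) - f[fdof]
    return u, reactions


def assemble_and_solve(
    model: TetModel,
    materials: MaterialSpec,
    load: LoadCase,
    fixed_nodes,
    K: sp.csr_matrix | None = None,
    lu=None,
):
    """Full pipeline for one case: assemble (or reuse), solve, postprocess.

    Returns (StressField, K, lu) so callers comparing several load cases can
    reuse the assembled matrix and (for distributed cases) its factorization.
    """
    if K is None:
        K = assemble_stiffness(model, materials)
    f = load.force_vector(model.n_nodes)
    if load.coupling == "kinematic":
        u, reactions = _solve_kinematic_coupling(K, f, load.node_ids, fixed_nodes)
    else:
        u, reactions, lu = solve_displacements(K, f, fixed_nodes, lu=lu)
    stress, strain = compute_stress(model, materials, u)
    vols = np.abs(model.element_volumes())
    energy = 0.5 * float(np.einsum("ei,ei,e->", stress, strain, vols))
    field = StressField(
        displacements=u.reshape(-1, 3),
        stress=stress,
        von_mises=von_mises(stress),
        principal=principal_stresses(stress),
        reactions=reactions,
        applied=f,
        strain_energy=energy,
    )
    return field, K, lu


@dataclass
class StressPath:
    """Stress samples at arc-length-uniform stations along a straight path."""

    element_ids: np.ndarray
    arc_positions: np.ndarray    # mm from the start point
    von_mises: np.ndarray        # MPa
    principal: np.ndarray        # (n, 3) MPa
    start: np.ndarray
    end: np.ndarray

    def to_records(self) -> list[dict]:
        return [
            {
                "arc_mm": float(self.arc_positions[i]),
                "element": int(self.element_ids[i]),
                "von_mises_mpa": float(self.von_mises[i]),
                "sigma1_mpa": float(self.principal[i, 0]),
                "sigma2_mpa": float(self.principal[i, 1]),
                "sigma3_mpa": float(self.principal[i, 2]),
            }
            for i in range(len(self.element_ids))
        ]


def extract_path(
    field: StressField,
    model: TetModel,
    start_point,
    end_point,
    n_samples: int = 12,
) -> StressPath:
    """Sample element stresses along the straight segment start -> end.

    Stations sit at the midpoints of ``n_samples`` equal arc-length bins
    (so ``n_samples=1`` samples the segment midpoint); each station reports
    the element whose centroid is nearest.
    """
    a = np.asarray(start_point, dtype=float).reshape(3)
    b = np.asarray(end_point, dtype=float).reshape(3)
    L = np.linalg.norm(b - a)
    if L < 1e-12:
        raise ParameterError("path endpoints coincide")
    if n_samples < 1:
        raise ParameterError("n_samples must be >= 1")
    t = (np.arange(n_samples) + 0.5) / n_samples
    stations = a + t[:, None] * (b - a)
    tree = cKDTree(model.element_centroids())
    _, eids = tree.query(stations)
    return StressPath(
        element_ids=np.asarray(eids, dtype=np.int64),
        arc_positions=t * L,
        von_mises=field.von_mises[eids],
        principal=field.principal[eids],
        start=a,
        end=b,
    )


def compare_load_cases(
    model: TetModel,
    materials: MaterialSpec,
    cases: dict,
    fixed_nodes,
    path_start=None,
    path_end=None,
    n_path_samples: int = 12,
    peak_region_tol_mm: float = 5.0,
    exclude_near_fixed_mm: float = 0.0,
) -> dict:
    """Solve every load case on a shared stiffness matrix and compare stresses.

    For each case the report holds the maximum cortical von Mises stress, the
    element where it occurs, its distance to the loaded region, a qualitative
    classifier ("peak_within_loaded_region" when that distance is below
    ``peak_region_tol_mm``), the equilibrium residual, and (when a path is
    given) the stress profile at ``n_path_samples`` stations.

    ``exclude_near_fixed_mm`` applies a Saint-Venant exclusion zone when
    locating the peak: elements whose centroid lies within that distance of a
    constrained node are ignored, since fully clamped boundaries produce
    mesh-dependent corner concentrations that say nothing about the loading
    cases being compared.
    """
    K = None
    lu = None
    labels = np.asarray(model.labels).astype(str)
    cortical = np.flatnonzero(labels == CORTICAL)
    if cortical.size == 0:
        cortical = np.arange(model.n_elements)
    centroids = model.element_centroids()
    if exclude_near_fixed_mm > 0:
        fixed_xyz = model.nodes[np.asarray(fixed_nodes, dtype=np.int64)]
        tree = cKDTree(fixed_xyz)
        d_fixed, _ = tree.query(centroids[cortical])
        cortical = cortical[d_fixed > exclude_near_fixed_mm]
        if cortical.size == 0:
            raise ParameterError("exclusion zone removed every cortical element")
    report: dict = {
        "cases": {},
        "element_type": model.element_type,
        "exclude_near_fixed_mm": float(exclude_near_fixed_mm),
    }
    fields: dict = {}
    for name, case in cases.items():
        fld, K, lu = assemble_and_solve(model, materials, case, fixed_nodes, K=K, lu=lu)
        fields[name] = fld
        vm_c = fld.von_mises[cortical]
        imax = cortical[int(np.argmax(vm_c))]
        peak_xyz = centroids[imax]
        d_loaded = float(
            np.min(np.linalg.norm(model.nodes[case.node_ids] - peak_xyz, axis=1))
        )
        entry = {
            "kind": case.kind,
            "total_force_n": [float(v) for v in case.total_force],
            "n_loaded_nodes": int(len(case.node_ids)),
            "max_cortical_von_mises_mpa": float(fld.von_mises[imax]),
            "peak_element": int(imax),
            "peak_location_mm": [float(v) for v in peak_xyz],
            "peak_distance_to_loaded_region_mm": d_loaded,
            "classifier": (
                "peak_within_loaded_region"
                if d_loaded <= peak_region_tol_mm
                else "peak_remote_from_loaded_region"
            ),
            "equilibrium_residual": fld.equilibrium_residual(),
            "load_metadata": dict(case.metadata),
        }
        if path_start is not None and path_end is not None:
            path = extract_path(fld, model, path_start, path_end, n_path_samples)
            entry["path"] = path.to_records()
        report["cases"][name] = entry
    report["_fields"] = fields  # in-memory only; stripped before serialization
    return report


def tet4_to_tet10(model: TetModel) -> TetModel:
    """Promote a linear tet mesh to straight-edged 10-node tetrahedra.

    Corner node ids are preserved, so node sets defined on the tet4 mesh
    remain valid; midside nodes are appended at edge midpoints.
    """
    if model.element_type != "tet4":
        raise ParameterError("tet4_to_tet10 expects a tet4 model")
    tets = model.elements
    edges = np.concatenate([tets[:, e] for e in TET10_EDGES])
    key = np.sort(edges, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    mid = 0.5 * (model.nodes[uniq[:, 0]] + model.nodes[uniq[:, 1]])
    nodes = np.vstack([model.nodes, mid])
    mid_ids = (len(model.nodes) + inv).reshape(6, -1).T  # (M, 6)
    elements = np.hstack([tets, mid_ids])
    return TetModel(
        nodes=nodes,
        elements=elements,
        labels=model.labels.copy(),
        node_sets={k: v.copy() for k, v in model.node_sets.items()},
        element_type="tet10",
    )
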