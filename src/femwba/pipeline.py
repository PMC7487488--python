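"""End-to-end orchestration: landmarks -> margin lines -> registration ->
weight-bearing patch -> finite-element load-case comparison.

Every run writes a manifest (parameters, stage outputs, SHA-256 checksums)
so that two runs with equal manifests are byte-identical — the
reproducibility substitute for the interactive multi-tool workflow the
method replaces.  Stages are individually callable and resume from the
files written by earlier stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import trimesh
import yaml

from . import io as fio
from .errors import ConfigError, FemwbaError
from .fe_solver import (
    MaterialSpec,
    TetModel,
    build_load_case,
    compare_load_cases,
    tet4_to_tet10,
)
from .radiograph_geometry import (
    build_boundary_construction,
    ce_angle,
    correct_magnification,
)
from .registration_projection import (
    coronal_plane,
    lift_line,
    project_to_plane,
    register_landmarks,
)
from .synthetic_anatomy import (
    FemurParams,
    generate_femur_surface,
    generate_radiograph,
    generate_tet_mesh,
    params_to_dict,
)
from .wba_surface import (
    apply_inferior_limit,
    elevation_mask,
    fit_head_sphere,
    halfspace_mask,
    monte_carlo_patch_area,
    smooth_patch_boundary,
    trim_by_margin_lines,
)

log = logging.getLogger(__name__)

#: Default hip loading for a 70 kg subject in simulated single-leg stance:
#: joint reaction force ~2.45 body weight through the head center, tilted
#: 16 deg laterally (coronal) and 10 deg posteriorly from vertical, pressing
#: infero-laterally onto the head.  Values are configuration defaults, not
#: reference results.
DEFAULT_JRF_N = 1715.0
DEFAULT_JRF_TILT_LATERAL_DEG = 16.0
DEFAULT_JRF_TILT_POSTERIOR_DEG = 10.0
#: Hip-abductor pull at the greater trochanter (~1.9 BW, 21 deg medial).
DEFAULT_ABDUCTOR_N = 1330.0
DEFAULT_ABDUCTOR_TILT_DEG = 21.0


def default_total_force(side: str = "left", magnitude: float = DEFAULT_JRF_N):
    lat = 1.0 if side == "left" else -1.0
    a = math.radians(DEFAULT_JRF_TILT_LATERAL_DEG)
    b = math.radians(DEFAULT_JRF_TILT_POSTERIOR_DEG)
    d = np.array([lat * math.sin(a), -math.sin(b), -math.cos(a) * math.cos(b)])
    return magnitude * d / np.linalg.norm(d)


def default_abductor_force(side: str = "left", magnitude: float = DEFAULT_ABDUCTOR_N):
    lat = 1.0 if side == "left" else -1.0
    a = math.radians(DEFAULT_ABDUCTOR_TILT_DEG)
    d = np.array([-lat * math.sin(a), 0.0, math.cos(a)])
    return magnitude * d


@dataclass
class PipelineConfig:
    """All inputs of a pipeline run; YAML round-trippable."""

    landmarks: str | None = None
    surface_mesh: str | None = None
    tet_mesh: str | None = None
    mesh_landmarks: str | None = None      # JSON {name: [x, y, z]} on the 3D model
    output_dir: str = "femwba_out"
    stages: tuple = ("landmarks", "registration", "wba", "fe")
    marker_true_diameter: float = 25.0
    limit_deg: float = 30.0
    fillet: bool = False
    fillet_radius: float = 1.0
    registration_names: tuple = ("p1", "p2", "p3", "p6", "p16", "p19")
    allow_scale: bool = True
    total_force: tuple | None = None       # N; default from side
    muscle_loads: tuple = ()               # ({point: [...], force: [...]}, ...)
    load_cases: tuple = ("A_patch", "B_circle", "C_point")
    circle_diameter: float = 20.0
    coupling: str = "kinematic"            # how surface loads are carried
    exclude_near_fixed_mm: float = 12.0    # Saint-Venant zone for peak reporting
    materials: dict | None = None          # label -> [E_mpa, nu]
    element_type: str = "tet4"
    path_end_mm: tuple | None = None       # head-neck junction point
    patch_node_tol: float = 2.5            # mm band selecting head-surface nodes
    mc_oracle_n: int = 200_000
    seed: int = 0
    side: str | None = None                # overrides landmark-file side if set
    log_level: str = "INFO"

    #: config keys holding paths, resolved relative to the YAML file location
    _PATH_KEYS = ("landmarks", "surface_mesh", "tet_mesh", "mesh_landmarks", "output_dir")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        base = Path(path).resolve().parent
        for key in cls._PATH_KEYS:
            if data.get(key):
                p = Path(data[key])
                data[key] = str(p if p.is_absolute() else base / p)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if not self.stages:
            raise ConfigError("at least one stage must be requested")
        known = {"landmarks", "registration", "wba", "fe"}
        bad = set(self.stages) - known
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        need_files = {"landmarks": self.landmarks}
        if "registration" in self.stages:
            need_files["mesh_landmarks"] = self.mesh_landmarks
        if "wba" in self.stages:
            need_files["surface_mesh"] = self.surface_mesh
        if "fe" in self.stages:
            need_files["tet_mesh"] = self.tet_mesh
        for key, val in need_files.items():
            if val is None:
                raise ConfigError(f"stage requires config key {key!r}")
            if not Path(val).exists():
                raise ConfigError(f"{key} file not found: {val}")
        if self.element_type not in ("tet4", "tet10"):
            raise ConfigError(f"element_type must be tet4 or tet10")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _materials(config: PipelineConfig) -> MaterialSpec:
    if config.materials is None:
        return MaterialSpec()
    return MaterialSpec(
        materials={k: (float(v[0]), float(v[1])) for k, v in config.materials.items()}
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages; returns the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "outputs": {}}
    state: dict = {}
    for stage in config.stages:
        try:
            _STAGES[stage](config, out, manifest, state)
        except FemwbaError as exc:
            raise type(exc)(
                f"stage {stage!r} failed: {exc} "
                f"(check the inputs listed in the manifest for this stage)"
            ) from exc
    manifest["checksums"] = {
        name: _sha256(path) for name, path in sorted(manifest["outputs"].items())
    }
    manifest["outputs"] = {k: str(v) for k, v in manifest["outputs"].items()}
    fio.write_json(manifest, out / "manifest.json")
    return manifest


def _stage_landmarks(config, out, manifest, state):
    lm = fio.read_landmarks_json(config.landmarks)
    if config.side:
        lm.side = config.side
    corrected = correct_magnification(lm)
    bc = build_boundary_construction(corrected)
    ce = ce_angle(corrected["p19"], corrected["p4"], corrected.side)
    state["landmarks"] = corrected
    state["boundary"] = bc
    report = {
        "side": corrected.side,
        "magnification_correction": lm.magnification_scale,
        "ce_angle_deg": ce,
        "W_mm": [float(v) for v in bc.W],
        "lateral_line": {
            "anchor_mm": [float(v) for v in bc.lateral_line.anchor],
            "direction": [float(v) for v in bc.lateral_line.direction],
            "patch_side_sign": bc.lateral_side_sign,
        },
        "medial_line": {
            "anchor_mm": [float(v) for v in bc.medial_line.anchor],
            "direction": [float(v) for v in bc.medial_line.direction],
            "patch_side_sign": bc.medial_side_sign,
        },
    }
    path = out / "boundary_construction.json"
    fio.write_json(report, path)
    manifest["stages"]["landmarks"] = {"ce_angle_deg": ce}
    manifest["outputs"]["boundary_construction.json"] = path


def _stage_registration(config, out, manifest, state):
    if "landmarks" not in state:
        _stage_landmarks(config, out, manifest, state)
    mesh_lm = {
        k: np.asarray(v, dtype=float)
        for k, v in json.loads(Path(config.mesh_landmarks).read_text()).items()
    }
    plane = coronal_plane()
    names = [n for n in config.registration_names if n in mesh_lm]
    source = {n: project_to_plane(mesh_lm[n], plane)[0] for n in names}
    target = {n: state["landmarks"][n] for n in names if n in state["landmarks"].points}
    reg = register_landmarks(source, target, allow_scale=config.allow_scale)
    state["registration"] = reg
    state["plane"] = plane
    path = out / "registration.json"
    fio.write_json(reg.to_dict(), path)
    manifest["stages"]["registration"] = {
        "rms_error_mm": reg.rms_error,
        "n_correspondences": len(reg.names),
    }
    manifest["outputs"]["registration.json"] = path


def _stage_wba(config, out, manifest, state):
    if "registration" not in state:
        _stage_registration(config, out, manifest, state)
    mesh = trimesh.load(config.surface_mesh, process=True)
    head = fit_head_sphere(mesh)
    plane = state["plane"]
    reg = state["registration"]
    bc = state["boundary"]
    lat3 = lift_line(bc.lateral_line, reg, plane)
    med3 = lift_line(bc.medial_line, reg, plane)
    total_force = np.asarray(
        config.total_force
        if config.total_force is not None
        else default_total_force(state["landmarks"].side),
        dtype=float,
    )
    u_up = -total_force / np.linalg.norm(total_force)
    # the patch side of each extruded line is the side holding the head center
    beta = trim_by_margin_lines(head, lat3, med3, plane, side_point=head.center)
    patch = apply_inferior_limit(
        beta, head, jrf_direction=u_up, limit_deg=config.limit_deg
    )
    if config.fillet:
        patch = smooth_patch_boundary(patch, config.fillet_radius)
    # independent oracle: same predicates, dense point sampling.  The sphere
    # integral only makes sense over the part of the sphere that is actual
    # head surface, so the oracle additionally keeps a sample point only when
    # its nearest mesh vertex belongs to the head region.
    predicates = _patch_predicates(head, bc, lat3, med3, plane, u_up, config.limit_deg)
    from scipy.spatial import cKDTree

    faces = np.asarray(mesh.faces)
    is_head_vert = np.zeros(len(mesh.vertices), dtype=bool)
    is_head_vert[np.unique(faces[head.head_facets])] = True
    vtree = cKDTree(mesh.vertices)

    def head_domain(points):
        _, idx = vtree.query(np.atleast_2d(points))
        return is_head_vert[idx]

    mc_area = monte_carlo_patch_area(
        head.center,
        head.radius,
        list(predicates) + [head_domain],
        n=config.mc_oracle_n,
        seed=config.seed + 1,
    )
    state.update(
        {
            "head": head,
            "patch": patch,
            "lines3": (lat3, med3),
            "u_up": u_up,
            "total_force": total_force,
            "predicates": predicates,
        }
    )
    sub = patch.submesh()
    stl_path = out / "patch.stl"
    stl_path.write_text(sub.export(file_type="stl_ascii"))
    facets_path = out / "patch_facets.json"
    fio.write_json(
        {
            "facets": [int(f) for f in patch.facets],
            "area_mm2": patch.area,
            "provenance": patch.provenance,
        },
        facets_path,
    )
    area_path = out / "area_report.json"
    centroid = patch.centroid()
    fio.write_json(
        {
            "area_mm2": patch.area,
            "monte_carlo_area_mm2": mc_area,
            "fitted_head_center_mm": [float(v) for v in head.center],
            "fitted_head_radius_mm": head.radius,
            "sphere_fit_rms_mm": head.fit_rms,
            "patch_centroid_mm": [float(v) for v in centroid],
            "n_facets": int(len(patch.facets)),
            "filleted": bool(config.fillet),
        },
        area_path,
    )
    manifest["stages"]["wba"] = {
        "area_mm2": patch.area,
        "monte_carlo_area_mm2": mc_area,
        "n_facets": int(len(patch.facets)),
    }
    manifest["outputs"].update(
        {
            "patch.stl": stl_path,
            "patch_facets.json": facets_path,
            "area_report.json": area_path,
        }
    )


def _patch_predicates(head, bc, lat3, med3, plane, u_up, limit_deg):
    """The three trimming predicates, shared by facet and point classification."""
    lat_sign = 1.0 if halfspace_mask(head.center[None], lat3, plane, 1.0)[0] else -1.0
    med_sign = 1.0 if halfspace_mask(head.center[None], med3, plane, 1.0)[0] else -1.0
    return [
        lambda p, s=lat_sign: halfspace_mask(p, lat3, plane, s),
        lambda p, s=med_sign: halfspace_mask(p, med3, plane, s),
        lambda p: elevation_mask(p, head.center, u_up, limit_deg),
    ]


def load_tet_model(path) -> TetModel:
    path = Path(path)
    if path.suffix.lower() == ".vtk":
        return fio.read_vtk(path)
    if path.suffix.lower() == ".inp":
        return fio.read_inp(path)
    raise ConfigError(f"unsupported tet mesh format: {path.suffix}")


def resolve_node_sets(model: TetModel, head, predicates, tol: float):
    """Geometric node sets: distal fixation, head surface, patch, apex."""
    z = model.nodes[:, 2]
    distal = np.flatnonzero(z < z.min() + 1e-9)
    bnodes = model.boundary_nodes()
    on_head = (
        np.abs(np.linalg.norm(model.nodes[bnodes] - head.center, axis=1) - head.radius)
        < tol
    )
    head_nodes = bnodes[on_head]
    if head_nodes.size == 0:
        raise ConfigError(
            "no tet-mesh boundary nodes lie on the fitted head sphere; "
            "check that surface and tet meshes describe the same anatomy"
        )
    keep = np.ones(len(head_nodes), dtype=bool)
    for pred in predicates:
        keep &= pred(model.nodes[head_nodes])
    patch_nodes = head_nodes[keep]
    apex = head_nodes[int(np.argmax(model.nodes[head_nodes, 2]))]
    return {
        "distal_fixed": distal,
        "head_surface": head_nodes,
        "patch_nodes": patch_nodes,
        "apex_node": np.array([apex]),
    }


def _stage_fe(config, out, manifest, state):
    if "patch" not in state:
        _stage_wba(config, out, manifest, state)
    model = load_tet_model(config.tet_mesh)
    if config.element_type == "tet10" and model.element_type == "tet4":
        model = tet4_to_tet10(model)
    head = state["head"]
    sets = resolve_node_sets(model, head, state["predicates"], config.patch_node_tol)
    model.node_sets.update(sets)
    if sets["patch_nodes"].size == 0:
        raise ConfigError("weight-bearing patch contains no tet-mesh surface nodes")
    total_force = state["total_force"]
    extra = []
    for item in config.muscle_loads:
        pt = np.asarray(item["point"], dtype=float)
        node = int(
            model.boundary_nodes()[
                np.argmin(np.linalg.norm(model.nodes[model.boundary_nodes()] - pt, axis=1))
            ]
        )
        extra.append((node, np.asarray(item["force"], dtype=float)))
    apex = int(sets["apex_node"][0])
    cases = {}
    for kind in config.load_cases:
        cases[kind[0]] = build_load_case(
            model,
            kind,
            total_force,
            patch_nodes=sets["patch_nodes"],
            circle_center=model.nodes[apex],
            circle_diameter=config.circle_diameter,
            apex_node=apex,
            candidate_nodes=sets["head_surface"],
            extra_loads=extra,
            coupling=config.coupling,
        )
    path_end = config.path_end_mm
    report = compare_load_cases(
        model,
        _materials(config),
        cases,
        sets["distal_fixed"],
        path_start=model.nodes[apex] if path_end is not None else None,
        path_end=np.asarray(path_end, dtype=float) if path_end is not None else None,
        exclude_near_fixed_mm=config.exclude_near_fixed_mm,
    )
    fields = report.pop("_fields")
    report["patch_area_mm2"] = state["patch"].area
    report["n_nodes"] = model.n_nodes
    report["n_elements"] = model.n_elements
    fe_path = out / "fe_comparison.json"
    fio.write_json(report, fe_path)
    manifest["outputs"]["fe_comparison.json"] = fe_path
    # per-station CSV table
    rows = []
    for name, entry in report["cases"].items():
        for rec in entry.get("path", []):
            rows.append({"case": name, **rec})
    if rows:
        import pandas as pd

        csv_path = out / "path_profiles.csv"
        pd.DataFrame(rows).to_csv(csv_path, index=False)
        manifest["outputs"]["path_profiles.csv"] = csv_path
    manifest["stages"]["fe"] = {
        name: {
            "max_cortical_von_mises_mpa": entry["max_cortical_von_mises_mpa"],
            "classifier": entry["classifier"],
        }
        for name, entry in report["cases"].items()
    }
    state["fe_report"] = report
    state["fe_fields"] = fields
    state["fe_model"] = model


_STAGES = {
    "landmarks": _stage_landmarks,
    "registration": _stage_registration,
    "wba": _stage_wba,
    "fe": _stage_fe,
}


# ---------------------------------------------------------------------------
# demo fixture
# ---------------------------------------------------------------------------

def make_demo_fixture(
    output_dir,
    seed: int = 0,
    target_ce_deg: float = 33.0,
    voxel_size: float = 2.0,
    surface_pitch: float = 1.2,
    element_type: str = "tet4",
    params: FemurParams | None = None,
) -> dict:
    """Write one complete synthetic volunteer (meshes, landmarks, config).

    Returns a dict of written paths; regenerating with the same seed yields
    identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or FemurParams(seed=seed)
    mesh, truth = generate_femur_surface(params, pitch=surface_pitch)
    tet = generate_tet_mesh(params, voxel_size=voxel_size)
    lm = generate_radiograph(
        truth, magnification=1.1, noise_sd=0.0, seed=seed, target_ce_deg=target_ce_deg
    )
    paths = {}
    surf_path = out / "femur_surface.stl"
    surf_path.write_text(mesh.export(file_type="stl_ascii"))
    paths["surface_mesh"] = surf_path
    tet_path = out / "femur_tet.vtk"
    fio.write_vtk(tet, tet_path)
    paths["tet_mesh"] = tet_path
    lm_path = out / "landmarks.json"
    fio.write_landmarks_json(lm, lm_path)
    paths["landmarks"] = lm_path
    mesh_lm_path = out / "mesh_landmarks.json"
    fio.write_json(
        {k: [float(x) for x in v] for k, v in truth.landmarks.items()}, mesh_lm_path
    )
    paths["mesh_landmarks"] = mesh_lm_path
    truth_path = out / "ground_truth.json"
    fio.write_json(
        {
            "head_center_mm": [float(v) for v in truth.head_center],
            "head_radius_mm": float(truth.head_radius),
            "magnification": 1.1,
            "target_ce_deg": float(target_ce_deg),
            "params": params_to_dict(params),
        },
        truth_path,
    )
    paths["ground_truth"] = truth_path
    # Joint reaction force only: in an isolated proximal femur with a fully
    # clamped distal end, concentrated muscle point loads mostly bend the
    # shaft into the clamp, so the demo keeps the loading to the JRF.
    F = default_total_force(params.side)
    config = PipelineConfig(
        landmarks="landmarks.json",
        surface_mesh="femur_surface.stl",
        tet_mesh="femur_tet.vtk",
        mesh_landmarks="mesh_landmarks.json",
        output_dir="results",
        total_force=tuple(float(v) for v in F),
        element_type=element_type,
        path_end_mm=tuple(float(v) for v in params.head_neck_junction_point),
        seed=seed,
    )
    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    paths["config"] = cfg_path
    return paths
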