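"""File formats: landmark JSON/CSV, legacy VTK, and a minimal Abaqus INP dialect.

VTK output is legacy ASCII UNSTRUCTURED_GRID (tet4 cell type 10, tet10 cell
type 24) with material labels as cell data and, optionally, displacement /
von Mises fields.  The INP dialect covers *NODE, *ELEMENT (C3D4 / C3D10),
*ELSET and *NSET blocks — enough to round-trip a labeled TetModel.

All writers format floats with ``repr``-faithful precision so identical
inputs produce byte-identical files.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .fe_solver import TetModel
from .radiograph_geometry import RadiographLandmarkSet

_F = "{:.10g}"


def _fmt(x: float) -> str:
    return _F.format(float(x))


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def write_landmarks_json(lm: RadiographLandmarkSet, path) -> None:
    data = {
        "side": lm.side,
        "marker": {
            "measured_mm": float(lm.marker_measured_diameter),
            "true_mm": float(lm.marker_true_diameter),
        },
        "points": {k: [float(v[0]), float(v[1])] for k, v in sorted(lm.points.items())},
    }
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


def read_landmarks_json(path) -> RadiographLandmarkSet:
    data = json.loads(Path(path).read_text())
    try:
        return RadiographLandmarkSet(
            points={k: np.asarray(v, dtype=float) for k, v in data["points"].items()},
            side=data.get("side", "left"),
            marker_measured_diameter=float(data["marker"]["measured_mm"]),
            marker_true_diameter=float(data["marker"]["true_mm"]),
        )
    except KeyError as exc:
        raise ParameterError(f"landmark JSON missing key: {exc}") from exc


def write_landmarks_csv(lm: RadiographLandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name", "x_mm", "y_mm"])
        for k in sorted(lm.points):
            w.writerow([k, _fmt(lm.points[k][0]), _fmt(lm.points[k][1])])


def read_landmarks_csv(
    path, side="left", marker_measured=25.0, marker_true=25.0
) -> RadiographLandmarkSet:
    points = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            points[row["name"]] = np.array([float(row["x_mm"]), float(row["y_mm"])])
    return RadiographLandmarkSet(
        points=points,
        side=side,
        marker_measured_diameter=marker_measured,
        marker_true_diameter=marker_true,
    )


# ---------------------------------------------------------------------------
# legacy VTK
# ---------------------------------------------------------------------------

_VTK_CELL = {"tet4": 10, "tet10": 24}
_CELL_VTK = {10: "tet4", 24: "tet10"}


def write_vtk(
    model: TetModel,
    path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write a TetModel (plus optional fields) as legacy ASCII VTK."""
    lines = [
        "# vtk DataFile Version 3.0",
        "femwba tetrahedral model",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {model.n_nodes} double",
    ]
    lines += [" ".join(_fmt(v) for v in p) for p in model.nodes]
    n_per = model.elements.shape[1]
    lines.append(f"CELLS {model.n_elements} {model.n_elements * (n_per + 1)}")
    lines += [f"{n_per} " + " ".join(str(int(i)) for i in el) for el in model.elements]
    lines.append(f"CELL_TYPES {model.n_elements}")
    lines += [str(_VTK_CELL[model.element_type])] * model.n_elements
    labels = np.asarray(model.labels).astype(str)
    uniq = sorted(set(labels.tolist()))
    label_id = {s: i for i, s in enumerate(uniq)}
    lines.append(f"CELL_DATA {model.n_elements}")
    lines.append("SCALARS material int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(label_id[s]) for s in labels]
    comment = "material ids: " + ", ".join(f"{i}={s}" for s, i in label_id.items())
    for name, arr in (cell_data or {}).items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [_fmt(v) for v in arr]
        else:
            lines.append(f"FIELD {name}_field 1")
            lines.append(f"{name} {arr.shape[1]} {len(arr)} double")
            lines += [" ".join(_fmt(v) for v in row) for row in arr]
    if point_data:
        lines.append(f"POINT_DATA {model.n_nodes}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2 and arr.shape[1] == 3:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(_fmt(v) for v in row) for row in arr]
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [_fmt(v) for v in np.ravel(arr)]
    Path(path).write_text("\n".join(lines) + f"\n# {comment}\n")


def read_vtk(path) -> TetModel:
    """Read a legacy ASCII VTK unstructured grid written by :func:`write_vtk`."""
    text = Path(path).read_text().splitlines()
    it = iter(range(len(text)))
    i = 0

    def tokens(line):
        return text[line].split()

    nodes = elements = cell_types = None
    labels = None
    label_names = {}
    while i < len(text):
        t = tokens(i)
        if not t:
            i += 1
            continue
        if t[0] == "POINTS":
            n = int(t[1])
            nodes = np.array(
                [[float(v) for v in tokens(i + 1 + k)] for k in range(n)]
            )
            i += n + 1
        elif t[0] == "CELLS":
            m = int(t[1])
            elements = [
                [int(v) for v in tokens(i + 1 + k)][1:] for k in range(m)
            ]
            i += m + 1
        elif t[0] == "CELL_TYPES":
            m = int(t[1])
            cell_types = {int(tokens(i + 1 + k)[0]) for k in range(m)}
            i += m + 1
        elif t[0] == "SCALARS" and t[1] == "material":
            m = len(elements)
            labels = np.array([int(tokens(i + 2 + k)[0]) for k in range(m)])
            i += m + 2
        elif t[0] == "#" and "material" in text[i]:
            # "# material ids: 0=cancellous, 1=cortical"
            part = text[i].split(":", 1)[1]
            for item in part.split(","):
                k, v = item.strip().split("=")
                label_names[int(k)] = v
            i += 1
        else:
            i += 1
    if nodes is None or elements is None or cell_types is None:
        raise ParameterError(f"{path} is not a VTK file this package can read")
    if len(cell_types) != 1:
        raise ParameterError("mixed cell types are not supported")
    etype = _CELL_VTK.get(next(iter(cell_types)))
    if etype is None:
        raise ParameterError("only tetrahedral VTK cells are supported")
    elements = np.array(elements, dtype=np.int64)
    if labels is None:
        str_labels = np.full(len(elements), "cortical")
    else:
        str_labels = np.array([label_names.get(int(v), str(v)) for v in labels])
    return TetModel(
        nodes=nodes, elements=elements, labels=str_labels, element_type=etype
    )


# ---------------------------------------------------------------------------
# minimal Abaqus INP dialect
# ---------------------------------------------------------------------------

def write_inp(model: TetModel, path) -> None:
    etype = "C3D4" if model.element_type == "tet4" else "C3D10"
    lines = ["*NODE"]
    for i, p in enumerate(model.nodes, start=1):
        lines.append(f"{i}, " + ", ".join(_fmt(v) for v in p))
    lines.append(f"*ELEMENT, TYPE={etype}")
    for e, el in enumerate(model.elements, start=1):
        lines.append(f"{e}, " + ", ".join(str(int(i) + 1) for i in el))
    labels = np.asarray(model.labels).astype(str)
    for label in sorted(set(labels.tolist())):
        ids = np.flatnonzero(labels == label) + 1
        lines.append(f"*ELSET, ELSET={label.upper()}")
        lines += _wrap_ids(ids)
    for name, ids in sorted(model.node_sets.items()):
        lines.append(f"*NSET, NSET={name.upper()}")
        lines += _wrap_ids(np.asarray(ids) + 1)
    Path(path).write_text("\n".join(lines) + "\n")


def _wrap_ids(ids, per_line: int = 12) -> list:
    ids = [str(int(i)) for i in ids]
    return [", ".join(ids[k : k + per_line]) for k in range(0, len(ids), per_line)]


def read_inp(path) -> TetModel:
    nodes: dict[int, list] = {}
    elements: dict[int, list] = {}
    elsets: dict[str, list] = {}
    nsets: dict[str, list] = {}
    etype = None
    section = None
    current = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            head = [p.strip() for p in line.split(",")]
            key = head[0].upper()
            opts = dict(
                p.split("=", 1) for p in (h.upper() for h in head[1:]) if "=" in p
            )
            if key == "*NODE":
                section = "node"
            elif key == "*ELEMENT":
                section = "element"
                etype = opts.get("TYPE", "C3D4")
            elif key == "*ELSET":
                section = "elset"
                current = opts.get("ELSET", "SET").lower()
                elsets.setdefault(current, [])
            elif key == "*NSET":
                section = "nset"
                current = opts.get("NSET", "SET").lower()
                nsets.setdefault(current, [])
            else:
                section = None
            continue
        vals = [v for v in (s.strip() for s in line.split(",")) if v]
        if section == "node":
            nodes[int(vals[0])] = [float(v) for v in vals[1:4]]
        elif section == "element":
            elements[int(vals[0])] = [int(v) for v in vals[1:]]
        elif section == "elset":
            elsets[current] += [int(v) for v in vals]
        elif section == "nset":
            nsets[current] += [int(v) for v in vals]
    if not nodes or not elements:
        raise ParameterError(f"{path} contains no *NODE/*ELEMENT data")
    node_ids = sorted(nodes)
    remap = {nid: k for k, nid in enumerate(node_ids)}
    node_arr = np.array([nodes[nid] for nid in node_ids])
    elem_ids = sorted(elements)
    eremap = {eid: k for k, eid in enumerate(elem_ids)}
    elem_arr = np.array(
        [[remap[v] for v in elements[eid]] for eid in elem_ids], dtype=np.int64
    )
    labels = np.full(len(elem_arr), "cortical", dtype=object)
    for name, ids in elsets.items():
        for eid in ids:
            labels[eremap[eid]] = name
    node_sets = {
        name: np.array([remap[i] for i in ids], dtype=np.int64)
        for name, ids in nsets.items()
    }
    return TetModel(
        nodes=node_arr,
        elements=elem_arr,
        labels=np.asarray(labels).astype(str),
        node_sets=node_sets,
        element_type="tet4" if etype.upper() == "C3D4" else "tet10",
    )


def write_nset_block(name: str, node_ids, path=None) -> str:
    """An *NSET block (1-based) for loading a patch in external FE tools."""
    lines = [f"*NSET, NSET={name.upper()}"] + _wrap_ids(np.asarray(node_ids) + 1)
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_json(data: dict, path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
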