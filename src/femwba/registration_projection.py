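"""Planar registration of the mesh's AP projection to the radiograph.

The 3D surface model is orthogonally projected along the anterior-posterior
direction onto a coronal *datum plane*; named landmarks shared between that
projection and the radiograph are registered with a closed-form least-squares
similarity transform (2D Procrustes / Umeyama).  Radiograph constructions
(the margin lines) are then *lifted* back through the inverse registration
onto the datum plane, where they can trim the femoral-head surface in 3D.

The registration is restricted to in-plane similarity (rotation, translation,
optional isotropic scale — 4 DOF); out-of-plane pose is deliberately not
estimated, which matches an acquisition protocol where X-ray and CT are taken
in the same fixed posture.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, RegistrationError
from .radiograph_geometry import Line2D


@dataclass(frozen=True)
class DatumPlane:
    """A reference plane with an orthonormal in-plane basis.

    ``normal`` is the projection direction (anterior-posterior for the AP
    view); ``basis`` is a (2, 3) array whose rows span the plane.
    """

    origin: np.ndarray
    normal: np.ndarray
    basis: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        B = np.asarray(self.basis, dtype=float).reshape(2, 3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ParameterError("plane normal must be a unit vector")
        G = B @ B.T
        if not np.allclose(G, np.eye(2), atol=1e-9) or np.abs(B @ n).max() > 1e-9:
            raise ParameterError("basis must be orthonormal and orthogonal to the normal")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "basis", B)


def coronal_plane(origin=(0.0, 0.0, 0.0)) -> DatumPlane:
    """The canonical AP datum plane: normal +y, basis (x, z).

    In-plane coordinates are therefore (medial-lateral, inferior-superior),
    matching the radiograph frame.
    """
    return DatumPlane(
        origin=origin,
        normal=np.array([0.0, 1.0, 0.0]),
        basis=np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
    )


def project_to_plane(points, plane: DatumPlane) -> np.ndarray:
    """Orthogonal projection along ``plane.normal``, in in-plane coordinates."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    return (P - plane.origin) @ plane.basis.T


def embed_in_plane(uv, plane: DatumPlane) -> np.ndarray:
    """Inverse of :func:`project_to_plane` for points on the plane itself."""
    U = np.atleast_2d(np.asarray(uv, dtype=float))
    return plane.origin + U @ plane.basis


@dataclass
class PlanarRegistration:
    """In-plane similarity transform  y = s R(theta) x + t."""

    rotation_deg: float
    translation: np.ndarray
    scale: float = 1.0
    rms_error: float = 0.0
    names: tuple = field(default_factory=tuple)
    residuals: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scale <= 0:
            raise ParameterError("registration scale must be positive")
        self.translation = np.asarray(self.translation, dtype=float).reshape(2)

    @property
    def matrix(self) -> np.ndarray:
        a = math.radians(self.rotation_deg)
        return self.scale * np.array(
            [[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]]
        )

    def transform(self, points) -> np.ndarray:
        P = np.atleast_2d(np.asarray(points, dtype=float))
        return P @ self.matrix.T + self.translation

    def inverse(self) -> "PlanarRegistration":
        Minv = np.linalg.inv(self.matrix)
        return PlanarRegistration(
            rotation_deg=-self.rotation_deg,
            translation=-(self.translation @ Minv.T),
            scale=1.0 / self.scale,
            rms_error=self.rms_error,
            names=self.names,
        )

    @classmethod
    def identity(cls) -> "PlanarRegistration":
        return cls(rotation_deg=0.0, translation=np.zeros(2), scale=1.0)

    def to_dict(self) -> dict:
        return {
            "rotation_deg": float(self.rotation_deg),
            "translation_mm": [float(v) for v in self.translation],
            "scale": float(self.scale),
            "rms_error_mm": float(self.rms_error),
            "names": list(self.names),
            "residuals_mm": {k: float(v) for k, v in self.residuals.items()},
        }


def register_landmarks(
    source: dict, target: dict, allow_scale: bool = True
) -> PlanarRegistration:
    """Closed-form least-squares similarity registration of named 2D points.

    Finds the transform T minimizing sum ||T(source[name]) - target[name]||^2
    over the names shared by both dictionaries (2D Procrustes with the
    Umeyama scale estimate; rigid when ``allow_scale`` is False).
    """
    names = sorted(set(source) & set(target))
    if len(names) < 2:
        raise RegistrationError(
            f"need at least 2 shared landmark names, got {len(names)}"
        )
    X = np.array([np.asarray(source[n], float).reshape(2) for n in names])
    Y = np.array([np.asarray(target[n], float).reshape(2) for n in names])
    mx, my = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mx, Y - my
    var_x = (Xc**2).sum() / len(names)
    if var_x < 1e-24:
        raise RegistrationError("all source points coincide; registration degenerate")
    S = (Yc.T @ Xc) / len(names)
    U, D, Vt = np.linalg.svd(S)
    sgn = np.sign(np.linalg.det(U @ Vt)) or 1.0
    C = np.diag([1.0, sgn])
    R = U @ C @ Vt
    scale = float(np.trace(np.diag(D) @ C) / var_x) if allow_scale else 1.0
    if scale <= 0:
        raise RegistrationError("registration collapsed to non-positive scale")
    t = my - scale * (R @ mx)
    fitted = X @ (scale * R).T + t
    res = np.linalg.norm(fitted - Y, axis=1)
    return PlanarRegistration(
        rotation_deg=math.degrees(math.atan2(R[1, 0], R[0, 0])),
        translation=t,
        scale=scale,
        rms_error=float(np.sqrt(np.mean(res**2))),
        names=tuple(names),
        residuals=dict(zip(names, res)),
    )


@dataclass(frozen=True)
class Line3D:
    """A line lying in a datum plane: 3D point plus unit 3D direction."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        d = np.asarray(self.direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n < 1e-300:
            raise ParameterError("3D line direction has zero length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "direction", d / n)


def lift_line(line: Line2D, reg: PlanarRegistration, plane: DatumPlane) -> Line3D:
    """Express a radiograph line on the datum plane in 3D.

    The inverse registration maps radiograph coordinates into the mesh's
    in-plane projection coordinates; the plane basis then embeds the result
    in 3D.  The lifted line lies exactly in the plane.
    """
    inv = reg.inverse()
    q = inv.transform([line.anchor, line.anchor + line.direction])
    p3 = embed_in_plane(q, plane)
    return Line3D(point=p3[0], direction=p3[1] - p3[0])


def project_line(line: Line3D, plane: DatumPlane) -> Line2D:
    """Project a 3D line (not parallel to the normal) into plane coordinates."""
    a = project_to_plane([line.point, line.point + line.direction], plane)
    return Line2D(anchor=a[0], direction=a[1] - a[0])
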