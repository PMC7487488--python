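"""2D landmark model and margin-line constructions on the AP pelvis radiograph.

The weight-bearing area of the femoral head is bounded on the radiograph by two
lines built from named anatomical landmarks (Genda-style construction):

* the **lateral margin** (line 4–M): anchored at the lateral acetabular edge
  (p4) along the internal bisector of the angle formed by the rays to the
  inferior teardrop margin (p7) and to the intersection of the posterior
  acetabular margin with the inferior femoral-head margin (p11);
* the **medial margin** (line 5–W): from the medial end of the sourcil (p5)
  through W, the midpoint between the most medial point of the femoral head
  (p6) and the lateral teardrop margin (p18).

All coordinates live in an internal frame with +x toward the patient's left
and +y superior, in millimetres after magnification correction.  ``side``
("left"/"right") determines which image direction is anatomically lateral.

Landmark names are ``p1`` .. ``p19``; ``p19`` is the femoral head center.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateGeometryError, MissingLandmarkError, ParameterError

log = logging.getLogger(__name__)

#: All landmark names of the full construction.
LANDMARK_NAMES = tuple(f"p{i}" for i in range(1, 20))

#: Landmarks actually consumed by the margin-line / CE-angle constructions.
CONSTRUCTION_LANDMARKS = ("p4", "p5", "p6", "p7", "p11", "p18", "p19")

_ANGLE_TOL = 1e-9


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,):
        raise ParameterError(f"expected a 2D point, got shape {a.shape}")
    return a


def lateral_sign(side: str) -> float:
    """+1 if anatomically lateral is +x (left hip), -1 for the right hip."""
    if side not in ("left", "right"):
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    return 1.0 if side == "left" else -1.0


@dataclass(frozen=True)
class Line2D:
    """An oriented 2D line through ``anchor`` with unit ``direction``."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "anchor", _as_point(self.anchor))
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n < 1e-300:
            raise DegenerateGeometryError("line direction has zero length")
        object.__setattr__(self, "direction", d / n)

    def point_at(self, t: float) -> np.ndarray:
        return self.anchor + t * self.direction

    def side_of(self, points) -> np.ndarray:
        """Signed cross product of the direction with anchor->point.

        Positive on the left of the oriented line, negative on the right.
        """
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.anchor
        return self.direction[0] * p[:, 1] - self.direction[1] * p[:, 0]


@dataclass
class RadiographLandmarkSet:
    """Named 2D landmarks plus the magnification marker measurement."""

    points: dict[str, np.ndarray]
    side: str = "left"
    marker_measured_diameter: float = 25.0
    marker_true_diameter: float = 25.0

    def __post_init__(self):
        lateral_sign(self.side)  # validates
        if self.marker_measured_diameter <= 0 or self.marker_true_diameter <= 0:
            raise ParameterError("marker diameters must be positive")
        self.points = {k: _as_point(v) for k, v in self.points.items()}

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise MissingLandmarkError(name) from None

    def require(self, names=LANDMARK_NAMES) -> None:
        for n in names:
            if n not in self.points:
                raise MissingLandmarkError(n)

    @property
    def magnification_scale(self) -> float:
        """Correction factor s = true / measured applied to restore true size."""
        return self.marker_true_diameter / self.marker_measured_diameter

    def mirrored(self) -> "RadiographLandmarkSet":
        """The contralateral-equivalent set: x -> -x, side flipped."""
        return RadiographLandmarkSet(
            points={k: np.array([-v[0], v[1]]) for k, v in self.points.items()},
            side="right" if self.side == "left" else "left",
            marker_measured_diameter=self.marker_measured_diameter,
            marker_true_diameter=self.marker_true_diameter,
        )

    def transformed(self, angle_deg: float, translation) -> "RadiographLandmarkSet":
        """Rigidly moved copy (used by equivariance checks)."""
        a = math.radians(angle_deg)
        R = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        t = _as_point(translation)
        return replace(
            self, points={k: R @ v + t for k, v in self.points.items()}
        )


@dataclass
class BoundaryConstruction:
    """The assembled 2D boundary of the weight-bearing area."""

    lateral_line: Line2D
    medial_line: Line2D
    W: np.ndarray
    head_center: np.ndarray
    scale: float
    #: sign of ``line.side_of(head_center)`` per line; the patch side.
    lateral_side_sign: float = field(default=0.0)
    medial_side_sign: float = field(default=0.0)


def correct_magnification(lm: RadiographLandmarkSet) -> RadiographLandmarkSet:
    """Restore true size by scaling every point about the image origin.

    The returned set has ``marker_measured_diameter == marker_true_diameter``,
    so re-applying the correction is the identity.
    """
    s = lm.magnification_scale
    return RadiographLandmarkSet(
        points={k: s * v for k, v in lm.points.items()},
        side=lm.side,
        marker_measured_diameter=lm.marker_true_diameter,
        marker_true_diameter=lm.marker_true_diameter,
    )


def lateral_margin_line(p4, p7, p11) -> Line2D:
    """Line 4–M: internal bisector of the angle 7–4–11, anchored at p4."""
    p4, p7, p11 = _as_point(p4), _as_point(p7), _as_point(p11)
    u1 = p7 - p4
    u2 = p11 - p4
    n1, n2 = np.linalg.norm(u1), np.linalg.norm(u2)
    if n1 < _ANGLE_TOL or n2 < _ANGLE_TOL:
        raise DegenerateGeometryError("p7 or p11 coincides with p4")
    u1, u2 = u1 / n1, u2 / n2
    s = u1 + u2
    if np.linalg.norm(s) < _ANGLE_TOL:
        raise DegenerateGeometryError("rays 4->7 and 4->11 are opposite; bisector undefined")
    return Line2D(anchor=p4, direction=s)


def medial_margin_line(p5, p6, p18) -> tuple[Line2D, np.ndarray]:
    """Line 5–W toward W = midpoint(p6, p18); returns (line, W)."""
    p5, p6, p18 = _as_point(p5), _as_point(p6), _as_point(p18)
    W = 0.5 * (p6 + p18)
    d = W - p5
    if np.linalg.norm(d) < _ANGLE_TOL:
        raise DegenerateGeometryError("p5 coincides with W = midpoint(p6, p18)")
    return Line2D(anchor=p5, direction=d), W


def ce_angle(head_center, p4, side: str = "left") -> float:
    """Center-edge angle of Wiberg, in degrees.

    Angle between the superior vertical ray from the head center and the ray
    to the lateral acetabular edge p4, positive when p4 is lateral of the
    vertical for the given ``side``.
    """
    c, p4 = _as_point(head_center), _as_point(p4)
    v = p4 - c
    if np.linalg.norm(v) < _ANGLE_TOL:
        raise DegenerateGeometryError("p4 coincides with the head center")
    lat = lateral_sign(side)
    return math.degrees(math.atan2(lat * v[0], v[1]))


def fit_circle(points) -> tuple[np.ndarray, float, float]:
    """Algebraic least-squares circle fit; returns (center, radius, rms).

    Cross-check helper for p19: fitting the femoral-head contour points
    (e.g. p3, p6, p16) should land near the given head-center landmark.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[0] < 3:
        raise ParameterError("circle fit needs at least 3 points")
    A = np.column_stack([2.0 * P, np.ones(len(P))])
    b = (P**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:2]
    r2 = sol[2] + c @ c
    if r2 <= 0 or not np.isfinite(r2):
        raise DegenerateGeometryError("circle fit is degenerate")
    r = math.sqrt(r2)
    rms = float(np.sqrt(np.mean((np.linalg.norm(P - c, axis=1) - r) ** 2)))
    return c, r, rms


def build_boundary_construction(lm: RadiographLandmarkSet) -> BoundaryConstruction:
    """Assemble both margin lines from a magnification-corrected landmark set.

    The head center (p19) must lie on the patch side of both lines; if it sits
    exactly on a line (or the configuration is otherwise suspicious) a warning
    is logged but the construction is still returned.
    """
    lm.require(LANDMARK_NAMES)
    if abs(lm.magnification_scale - 1.0) > 1e-9:
        log.warning(
            "landmark set does not look magnification-corrected "
            "(scale=%.6f); call correct_magnification first",
            lm.magnification_scale,
        )
    lat_line = lateral_margin_line(lm["p4"], lm["p7"], lm["p11"])
    med_line, W = medial_margin_line(lm["p5"], lm["p6"], lm["p18"])
    c = lm["p19"]
    s_lat = float(np.sign(lat_line.side_of(c)[0]))
    s_med = float(np.sign(med_line.side_of(c)[0]))
    if s_lat == 0.0 or s_med == 0.0:
        log.warning("head center lies exactly on a margin line; patch side ambiguous")
    return BoundaryConstruction(
        lateral_line=lat_line,
        medial_line=med_line,
        W=W,
        head_center=c,
        scale=lm.magnification_scale,
        lateral_side_sign=s_lat,
        medial_side_sign=s_med,
    )
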