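# Methods

This note records the models, numerical choices and limitations behind
`femwba`, in the order the pipeline runs them.

## Coordinate conventions

All 3D geometry lives in a patient frame with **+x toward the patient's
left**, **+y anterior**, **+z superior**, lengths in mm. The AP projection
drops the y coordinate; the radiograph frame is (x, y) with +y superior.
`side` ("left"/"right") determines which image direction is anatomically
lateral (+x is lateral for a left hip). Mirroring a landmark set negates x
and flips `side`; all constructions are equivariant under this mirror and
under in-plane rigid motions (property-tested).

## Synthetic anatomy

The parametric proximal femur is the smooth union of three signed-distance
primitives: a head sphere (radius default **24 mm**), a neck capsule
(radius 15 mm, length 38 mm, neck-shaft angle 130°) and a shaft capsule
(radius 14.5 mm, length 70 mm) whose hemispherical top doubles as a
greater-trochanter prominence. Defaults are conventional adult dimensions;
no subject-specific values exist to reproduce. Two deliberate choices:

* **Smooth union** (`blend_radius`, default 8 mm, polynomial smooth-min).
  A sharp CSG union leaves a reentrant crease at the neck-shaft junction
  that behaves as an artificial stress concentrator whose FE stress grows
  without bound under mesh refinement. Real femurs have a broad, smooth
  calcar transition; the blend models that and leaves the head surface
  exactly spherical wherever the neck/shaft distance field exceeds
  `blend_radius`.
* **Voxel-template tetrahedral meshing.** Interior voxels of the signed
  distance field are split by a fixed cube template (6-tet Kuhn by default;
  a parity-mirrored 5-tet template is available). Both templates are
  face-conforming, all element volumes are positive by construction, and
  the mesh is deterministic. Elements are labeled *cortical* when their
  centroid lies within `cortical_thickness` (default 3 mm) of the outer
  surface, else *cancellous*. This single-thickness labeling is a
  simplification: real subchondral bone at the head is thinner than
  diaphyseal cortex.

The synthetic radiograph projects the femur-side landmark ground truth
(p1, p2, p3, p6, p16, p19) vertically, places the pelvis-side landmarks
from configurable offsets around the projected head center — chosen once to
mimic typical adult AP anatomy (teardrop ≈ 26–28 mm medial of the head
center, sourcil medial end at ~35° medial elevation, posterior-wall/
inferior-head intersection on the medial half of the head) — and puts `p4`
exactly at the requested CE angle, so the construct-then-measure CE round
trip is exact by design. Magnification scales every point about the image
origin; landmark noise is isotropic Gaussian at film scale; the coin marker
(true diameter 25 mm, configurable) measures `magnification × 25` mm.

What the generator does **not** emulate: real acetabular shape and
orientation (pelvis landmarks are offsets, not anatomy), out-of-plane pose
differences between X-ray and CT, cartilage, and intensity images of any
kind. Passing tests therefore validate the geometric construction and the
solver, not landmark identification on clinical films.

## Magnification, margin lines, CE angle

Scaling is about the image origin; every downstream construction is
translation-equivariant, so the origin choice is immaterial. The lateral
margin line takes the **internal** bisector branch (unit-vector sum of the
rays 4→7 and 4→11), correct because the weight-bearing margin lies inside
the acetabular arc; the construction is exact to 1e-12 over randomized
configurations. The CE angle is signed positive when `p4` is lateral of the
vertical through `p19` for the given side.

## Registration

Closed-form 2D similarity Procrustes (Umeyama) over named correspondences,
default set `p1, p2, p3, p6, p16, p19`. In-plane only (4 DOF): the intended
acquisition fixes posture between X-ray and CT, and estimating out-of-plane
pose from one projection is ill-posed. Scale is allowed by default (it
absorbs residual magnification error); a rigid option exists for
pre-corrected inputs. Exact on noise-free data to machine precision;
reflections are excluded (determinant-constrained rotation).

## Sphere fit and patch trimming

The head sphere is fitted by linear least squares with iterative vertex
re-selection: a coarse band (5% of radius) finds the region, then a tight
band (1%) refines center and radius so that slightly off-sphere vertices on
the blended junction cannot bias the fit (radius recovery error ~0.1% on
the default synthetic femur; the generator contract requires < 0.5%).
`head_facets` are collected afterwards with the looser band to keep
junction-adjacent, near-spherical surface available for trimming. A fit
whose rms exceeds 10% of the radius, or whose radius dwarfs the mesh, is
rejected.

Trimming is **facet-level classification**, not mesh Booleans: a facet is
kept when its centroid passes all three half-space/elevation tests. The
margin lines (lifted into the coronal datum plane) are extruded along the
plane normal; the patch side of each is the side containing the fitted head
center. The inferior limit keeps facets whose elevation above the
horizontal plane through the center is ≥ −30° (parameter `limit_deg`), with
the superior sense given by the outward JRF axis — because that axis has an
anterior component under the default load, the patch centroid lands
anterior as well as superior of the center, reproducing the expected
dome/anterolateral crescent. If trimming leaves several edge-connected
islands, the largest is kept and the count is recorded in the patch
provenance. Boundary error is controlled by mesh refinement and quantified
by the oracle below.

**Monte-Carlo oracle.** Patch areas are cross-checked against a dense
uniform sampling of the fitted sphere classified by the *same* predicate
functions (shared code path). On pure-sphere fixtures the two agree well
within 1% at 20k facets. On the synthetic femur the sphere integral is only
meaningful over the part of the sphere that is actual head surface, so the
shared domain is restricted: exactly (polar angle ≥ 75° from the neck axis,
which excludes the blended junction band) in the verification fixtures, and
approximately (nearest-mesh-vertex membership in the head region) for the
runtime cross-check the pipeline writes into `area_report.json`.

**Fillet.** The optional boundary fillet (default radius 1 mm, off by
default) rounds convex boundary corners by arc-cutting in the local tangent
plane and drops facets inside the cut triangles; concave corners are left
alone so smoothing never adds area. Reported areas exclude filleting unless
requested, since smoothing exists to ease FE post-processing, not to define
the patch.

## Finite elements

Isoparametric TET4 (constant-strain) elements by default; straight-edged
TET10 with 4-point Gauss quadrature behind the same interface. Units are
fixed N–mm–MPa. Material defaults — cortical E = 16 800 MPa, ν = 0.3;
cancellous E = 840 MPa, ν = 0.2 — are conventional literature values and
are configuration inputs, never test ground truth. The global system is
solved by sparse LU in symmetric mode; the patch test (constant strain from
affine boundary data) is reproduced to 1e-10 and global equilibrium
Σ reactions + Σ loads = 0 holds to 1e-8 relative on every solve. Verified
against closed forms: uniaxial compression (exact), cantilever tip
deflection within 10% of Euler–Bernoulli + Timoshenko shear at ≥ 8 elements
through the thickness (measured ≈ 7% with TET4, ≈ 0.8% with TET10).

**Load cases.** The JRF default is 2.45 body weight for a 70 kg subject
(1715 N), directed onto the head 16° lateral and 10° posterior of vertical
— a single-leg-stance hip contact force of textbook magnitude and
orientation. Surface loads are resolved to tributary-area nodal forces
(area-consistent; resultant preserved exactly). Two realizations of "the
force acts on this surface" are provided:

* **distributed** — the tributary nodal forces applied directly;
* **kinematic** (pipeline default) — the region's nodes are additionally
  tied to a common translation, i.e. a rigid, non-rotating coupling
  surface, which is how commercial solvers apply loads through coupling
  constraints.

The choice matters: a distributed 2 cm circle load produces only a mild
local stress (~20 MPa here) that is dominated by ordinary neck bending,
whereas the coupled circle shows the classic punch-edge concentration.
Since the comparison the package exists for contrasts load-*surface*
definitions as used in practice, the pipeline couples cases A and B (case C
is a single node either way) and records the realization in the load
metadata. Muscle forces can be supplied as extra point loads, but the demo
applies the JRF only: a concentrated abductor force on an isolated,
distally clamped femur mostly bends the shaft into the clamp — an artifact
of the truncated model, not a physiological effect.

**Peak reporting.** Maximum cortical von Mises stress per case, with a
Saint-Venant exclusion zone (`exclude_near_fixed_mm`, demo 12 mm) around
the clamped distal nodes: fully fixed boundaries generate mesh-dependent
corner concentrations that carry no information about the load cases being
compared. A peak within 5 mm of the loaded region is classified
"peak_within_loaded_region". The stress path from the head apex to the
head-neck junction is sampled at 12 arc-length-uniform stations (midpoints
of equal bins, so one sample sits at the segment midpoint), each reporting
the nearest element's principal and von Mises stresses.

## Problem sizes

The shipped demo uses a 1.2 mm marching-cubes surface (~32k facets), a
2.0 mm TET4 volume mesh (~96k elements — comparable to the scale of
clinical proximal-femur models), a 200k-sample runtime oracle, and 10⁶
samples in the verification fixtures. The full pipeline runs in about two
minutes on one CPU.

## Known limitations

* Landmarks are input coordinates; no image processing is performed.
* In-plane registration cannot correct sagittal pose differences.
* Facet-level trimming leaves a one-facet-scale ragged boundary; areas
  converge with mesh refinement and are bounded by the oracle.
* Single cortical thickness; no cartilage; linear elasticity only.
* The kinematic coupling is translation-only (the coupled surface cannot
  rotate); for the near-normal loads used here the restraint moment is
  small, but it is a stiffer idealization than a distributing coupling.
* Case C's apical point load is singular: its peak stress magnitude is
  mesh-dependent by nature and only its location is meaningful.
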