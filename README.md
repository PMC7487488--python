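# femwba

Quantifying the **weight-bearing area of the femoral head** in standing
position from an AP pelvis radiograph, and comparing proximal-femur
finite-element stress fields under three joint-load surface definitions.

## The problem

Isolated finite-element models of the femur need a load surface for the hip
joint reaction force (JRF). Most studies place the force on an arbitrary
circle at the top of the femoral head, or on a single apical node — but the
true load-transmitting region in standing is an individual, crescent-shaped
patch on the dome of the head. Its position and size change the computed
stress field substantially.

`femwba` implements a radiograph-driven construction of that patch:

1. **Landmarks.** 19 named points (`p1`…`p19`) are identified on a
   magnification-corrected AP radiograph (a coin marker of known diameter
   restores true scale: every point is scaled by
   *s = d_true / d_measured*).
2. **Margin lines** (after Genda's hip contact-area construction):
   * lateral margin, line 4–M: the internal bisector of the angle ∠7–4–11
     at the lateral acetabular edge `p4`;
   * medial margin, line 5–W: from the medial sourcil end `p5` through
     `W = (p6 + p18)/2`.
3. **2D→3D registration.** The 3D femur surface is orthogonally projected
   onto a coronal datum plane; named landmarks shared with the radiograph
   are registered by closed-form 2D similarity Procrustes (rotation,
   translation, optional scale). The margin lines are lifted through the
   inverse registration onto the datum plane.
4. **Trimming.** The femoral-head sphere is fitted (iterative least
   squares); head facets are kept when they lie on the head-center side of
   both extruded margin lines and above the −30° elevation limit relative
   to the horizontal plane through the head center (superior sense taken
   from the JRF axis). The kept facets are the weight-bearing patch;
   its area is the facet-area sum, cross-checked by a Monte-Carlo spherical
   surface integral using the very same classification predicates.
5. **FE comparison.** A bi-material (cortical/cancellous) linear-elastic
   tetrahedral solver (TET4, optionally TET10) runs three load cases with
   the distal shaft fully clamped:
   * **A** – JRF over the quantified patch,
   * **B** – JRF over a 2 cm circle at the head apex,
   * **C** – JRF at the single apical node,

   and reports each case's maximum cortical von Mises stress, its location
   relative to the loaded region, and a 12-station stress profile along the
   path from the head apex to the head-neck junction.

Because no scan data ship with the package, a **synthetic anatomy** module
generates a parametric proximal femur (head sphere + neck and shaft
capsules, smoothly blended), its voxel-template tetrahedral mesh, and a
matched synthetic radiograph with exact ground truth — every stage is
testable against known answers.

## Worked example

```bash
femwba demo --out demo --seed 0
```

generates one synthetic volunteer (surface STL, 2 mm tetrahedral mesh,
landmark JSON with a 1.1× magnification and CE angle 33°) and runs the full
pipeline. Typical output (`demo/results/`):

```
landmarks     ce_angle_deg                 33.0
registration  rms_error_mm                 7.5e-15   (6 correspondences)
wba           area_mm2                     1810.7
              monte_carlo_area_mm2         1834.7
fe            A  max cortical vM  41.0 MPa  peak_remote_from_loaded_region
              B  max cortical vM 120.0 MPa  peak_within_loaded_region
              C  max cortical vM 1042 MPa   peak_within_loaded_region
```

Reading: the magnification correction and registration recover the film
geometry exactly; the patch is a ~1800 mm² crescent on the dome of the
head, its centroid superior and anterior of the head center, with the
facet-sum area and the independent Monte-Carlo oracle agreeing within 2%.
Under the patch load (case A) the cortical stress peak sits at the
neck/calcar region, far from the loaded surface — the physiological
load-transfer pattern — whereas the circle and point loads (B, C)
concentrate stress directly under the load surface, the artifact the
quantified patch avoids.

Other entry points: `femwba landmarks validate`, `femwba wba compute`,
`femwba fe run`, `femwba fe compare`, `femwba report` (exit codes:
0 success, 2 configuration error, 3 computation error). The library API
mirrors the pipeline stage by stage; see the module docstrings.

## Layout

```
src/femwba/
  synthetic_anatomy.py        parametric femur, tet meshing, radiograph synthesis
  radiograph_geometry.py      landmark model, margin lines, CE angle
  registration_projection.py  datum plane, 2D Procrustes, line lifting
  wba_surface.py              sphere fit, trimming, area, MC oracle, fillet
  fe_solver.py                TET4/TET10 elasticity, load cases, stress paths
  pipeline.py / cli.py        orchestration, demo fixture, CLI
docs/methods.md               model assumptions, parameters, limitations
```
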