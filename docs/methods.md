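# Methods

`phmorph` automates a measurement protocol for proximal-humerus morphometry
on triangulated surface meshes, of the kind produced by segmenting clinical
CT and exporting an STL/PLY surface. This note records the model, the
estimators, the synthetic data used for validation, and the numerical
choices, in enough detail to reproduce or audit any number the package
prints.

## The measurement model

Five parameters describe the proximal humerus for implant design:

* **Neck-shaft (inclination) angle** `α` — angle between the head axis and
  the humeral shaft axis, degrees.
* **Humeral head height** `HHH` — distance from the center of the
  articular-surface circle (point B) to the head apex (point A), mm.
* **Articular surface diameter** `ASD` — diameter of the best-fit circle at
  the base of the articular surface in the anatomical-neck plane, mm.
* **Humeral head diameter** `HHD` — diameter of the sphere best fitting the
  articular head (center E), mm.
* **Medial offset** — perpendicular distance from the shaft axis to E, mm.

The protocol assumes the articular surface is approximately a spherical cap
truncated by the anatomical-neck plane. For an ideal cap of sphere radius
`R = HHD/2` and height `h = HHH`, the base-circle radius obeys the
spherical-cap identity `r² = h (2R − h)`, i.e. `ASD = 2√(HHH·(HHD − HHH))`.
Real heads are mildly aspheric; the pipeline reports fit residuals so the
user can judge how far a given bone departs from the model. `HHD ≥ ASD` is
deliberately not enforced.

## Pipeline stages and estimators

Input: a surface mesh in millimetres (units are asserted, never inferred)
and three anatomical-neck ridge landmarks — one at the junction of the
articular surface and greater tuberosity, two on the anteroinferior and
posteroinferior articular margins.

1. **Neck plane.** Total-least-squares plane through the landmarks (exact
   for three points). Orientation rule: the *head* side of the plane is the
   side with the smaller maximal extent — the head cap reaches at most one
   head-height above the plane, while the shaft extends several
   head-diameters below it. If one side is empty (a head-only mesh resting
   on the plane), the occupied side is the head side; a mesh lying entirely
   in the plane is an error.
2. **Articular circle (B, ASD).** The mesh–plane intersection contour is
   collected from edges strictly crossing the plane plus vertices lying on
   the plane within a scale-relative tolerance (1e-9 × bounding-box
   diagonal — this catches meshes whose vertex rings coincide exactly with
   the plane, where no edge strictly crosses). When the section yields
   several connected components (noise comparable to edge length fragments
   it), every component whose mean radial deviation from the circumcircle of
   the three landmarks is below 25 % of that circle's radius is kept and
   merged; the fallback is the single component nearest the landmarks. The
   contour is projected into the plane and fitted with an algebraic (Kåsa)
   circle plus one geometric Gauss–Newton pass. A config switch
   (`circle_from_landmarks`) restricts the fit to the three landmarks alone.
3. **Head sphere (E, HHD).** Vertices more than `head_margin_mm` (default
   0.5 mm) above the oriented plane feed an algebraic sphere fit (linearised
   normal equations) with one Gauss–Newton pass. One trim pass follows:
   vertices with absolute residual above 2× the RMS are discarded and the
   sphere refit — a stand-in for the manual exclusion of tuberosity
   vertices, whose outward displacement is large against the residual scale
   of the articular surface. On noise-free spherical data the trim is a
   no-op (an absolute floor of 1e-9 mm prevents trimming on residuals of
   pure rounding size).
4. **Apex (A).** Two definitions are available. `apex_method="vertex"` takes
   the mesh vertex with maximal signed distance from the neck plane (ties
   broken by lowest vertex index). The default, `apex_method="sphere"`,
   intersects the ray from B along the oriented plane normal with the fitted
   head sphere (far intersection). The two coincide for an ideal cap — a
   property the tests check — but the vertex rule is an extreme-value
   statistic: under surface noise the arg-max over the many near-apex
   vertices is biased outward by roughly the noise amplitude times the
   expected maximum of that many standard normals, and worse, it is biased
   *laterally* by several millimetres (any vertex within the noise band of
   the true apex can win), which corrupts the angle through the B→A
   direction. The model-based apex pools thousands of vertices through the
   sphere fit and is stable at the hundredth-of-a-millimetre level, so it is
   the default; the vertex apex remains available and is reported in the
   measurement frame.
5. **Shaft axis (g).** The provisional direction is the first principal
   direction of all mesh vertices, oriented away from the apex. The
   metaphyseal band holds vertices whose depth below B along this direction
   lies in `[1.0, 2.5] × HHD_provisional` (the provisional head diameter
   from stage 3); the bounds are config-overridable since no standard
   defines where the metaphyseal cylinder begins. Within the band the axis
   is fitted by the slice-centroid method: bin the points into slabs
   perpendicular to the current direction, fit a total-least-squares line
   through the slab centroids, re-slice along the fitted direction, and
   repeat until the direction stabilises (at most 5 passes). Three
   safeguards make this robust:
   * *End-slab trimming.* The band's cutting planes are perpendicular to the
     provisional direction, which may be several degrees off the true axis;
     the boundary slabs then hold partially-cut cross-sections whose
     centroids sit up to `2r/π` off-axis. The band fit bins into
     `n_slices + 2` slabs and drops the two boundary slabs.
   * *Gap-snapped slab boundaries.* Meshes reconstructed from tomographic
     slices are layered — vertices cluster in discrete rings. A slab
     boundary landing on a ring splits it into two arcs with strongly
     off-axis centroids; worse, a near-rational ratio of slab width to ring
     spacing can place *every other* boundary on a ring. Each nominal
     boundary is therefore moved to the midpoint of the widest sampling gap
     within a quarter slab-width; for continuously sampled clouds this is a
     no-op.
   * *Centroid outlier gate.* After each pass, centroids whose perpendicular
     residual against the fitted line exceeds 3× the median residual are
     dropped and the line refit once.
   The final direction is oriented proximal→distal.
6. **Parameters.** `α` = angle between B→A and the distal shaft direction
   (obtuse, ≈131° for anatomical inputs); `HHH = |AB|` (for an ideal cap
   this equals the distance along the plane normal; on real bones the two
   may differ and the Euclidean reading is used); `ASD` and `HHD` are the
   fitted diameters; the medial offset is the unsigned distance from E to
   the axis. Multiple observers' results are combined by the arithmetic
   mean per parameter (`average_observers`).

All stages are deterministic linear algebra with no random initialisation:
the pipeline is exactly reproducible, rigid-motion equivariant to ~1e-13
relative, and scale-equivariant.

## Synthetic anatomy

`generate_humerus` builds a parametric proximal humerus with exact ground
truth: a spherical cap (the head) truncated by the neck plane, joined by a
straight conical blend to a cylindrical shaft. In the canonical frame the
shaft axis runs along −z, the medial direction is +x, and the head axis
lies in the xz-plane at the configured neck-shaft angle to the distal
direction; the sphere center is displaced medially by the configured offset.
Landmarks sit on the analytic rim circle at 0°/120°/240°, optionally
jittered along the rim. Ground truth (all five parameters, apex, sphere and
circle centers, neck plane, shaft axis) is computed from the construction
before any noise; the cap identity holds exactly by construction.

Defaults and rationale:

* Parameter defaults are the cohort means of the study population the
  package's statistics module models (HHD 44.86 mm, HHH 14.31 mm, angle
  131.25°, offset 6.25 mm); the recovery grid spans the published min–max
  of each parameter (HHD 38.2–58.1, HHH 10.4–17.5, angle 114.20–143.07°,
  offset 1.1–11.2).
* `shaft_radius` 10 mm, `shaft_length` 150 mm — a realistic metaphyseal
  radius, and enough shaft to contain the default band (2.5 × the largest
  HHD below the neck plane).
* `mesh_resolution` 48 000 vertices ≈ 0.5 mm vertex spacing — the surface
  density of 3D models reconstructed from 1 mm-slice clinical CT, whose
  exported surfaces typically run to ~1e5 facets.
* `vertex_noise_sd` (isotropic Gaussian, default 0) models segmentation
  noise; 0.3 mm is used in the noisy validation condition.

What the generator does *not* emulate: head asphericity, the greater/lesser
tuberosities (a displaced-patch stand-in is used in tests of the trim pass),
cortical thickness, anisotropic segmentation error, and anatomical
retroversion (the head axis stays in the medial plane; rigid-motion tests
randomise the frame instead). Passing recovery tests therefore demonstrate
correctness of the geometric estimators under the stated model, not
clinical accuracy on real bones. The blend cone is synthetic plumbing whose
vertices lie strictly between the neck plane and the metaphyseal band; the
mesh is manifold on the cap and cylinder, and watertightness of the blend
seams is not guaranteed (nor needed by any stage).

## Synthetic cohorts and statistics

`generate_cohort` draws per-subject records matching the published summary
structure: 24 male / 46 female; per-sex means and SDs for all five
parameters; pairwise correlations 0.528 (HHD–HHH), 0.916 (HHD–ASD), 0.679
(ASD–HHH); height–parameter correlations 0.13/0.30/0.64/0.62/0.07. Within
each sex, (height, HHH, ASD, HHD) come from a multivariate normal assembled
from those values; correlations not supplied are filled by the product
heuristic `corr(a,b) ≈ corr(a,c)·corr(c,b)` through a shared variable, and
the matrix is projected to the nearest positive-semidefinite correlation
matrix by eigenvalue clipping (declared, not hidden). The angle and offset
are drawn independently per sex (their sex differences are configured as
null); age and weight are independent of the parameters; BMI is derived,
not drawn. Ethnicity is multinomial with the published proportions and
independent of everything — a true null, so ethnicity ANOVAs on generated
cohorts are exact type-I-error experiments. Caveats on the published inputs: the
published per-sex height distributions are not available, so the pooled
height distribution (157.35 ± 12.98 cm) is used within each sex; normality
is assumed throughout (the study's own screen passed); parameters are
clipped at a tiny positive floor (1e-6) to honour positivity — the
distortion is orders of magnitude below the tested moments. Some published
correlation/p pairs are mutually inconsistent at n = 70 (e.g. r = 0.3
reported with p < 0.001); the generator takes the r values at face value.

The statistics battery mirrors the study's analysis plan: KS normality
screen (plain by default; Lilliefors-corrected by config — the plain
variant matches the named method, the corrected one is statistically
preferable when moments are estimated), pooled/Welch t from summaries or
raw data, Mann-Whitney U (normal approximation with tie and continuity
corrections) for skewed data, Pearson/Spearman correlations, one-way
ANOVA / Kruskal-Wallis across groups with fewer-than-2-member groups
dropped. `t_from_summary` is authored from the textbook formulas and
cross-checked in the tests against an independent library implementation;
the pooled form on raw-data summaries equals the raw-data pooled t exactly
(an algebraic identity, also tested). Both pooled and Welch t are printed
in reports because the published table does not say which was used — and
two of its five rows (angle, HHD) are not reproducible from their own
printed summaries under either formula; those rows are excluded from
validation. No multiple-testing adjustment is applied, matching the study;
a warning is logged whenever a multi-test report is produced.

## Numerical choices and tolerances

* Degeneracy: collinearity/coplanarity at relative tolerance 1e-9;
  linear-system condition number capped at 1e8. Violations raise
  `DegenerateGeometryError` rather than returning garbage.
* Unit vectors are validated to 1e-9; a circle center must lie on its plane
  within 1e-6 mm.
* Gauss–Newton refinement is a single pass for the sphere and circle fits —
  the algebraic solutions are already consistent, and one pass removes
  their curvature bias while keeping the estimator closed-form and
  deterministic.
* Validation tolerances: noise-free recovery is exact to machine precision
  and tested at 1 % (angle 0.5°); with 0.3 mm vertex noise at 3 % (1.5°).
  The medial offset is additionally compared with an absolute floor of
  0.1 mm: a relative band on a ~1 mm offset would demand ~0.03 mm accuracy,
  which sits below the information floor of the axis fit at that noise
  level (a Cramér–Rao bound on the band points gives ~0.015 mm 1σ at the
  sphere center even for an optimal estimator), and 0.1 mm is the bound the
  zero-offset validation case uses.
* Problem sizes used by the validation suite: 27 bones per grid condition
  at 48 000 vertices; 20 rigid transforms; trivariate correlation recovery
  at n = 5 000; 2 000 simulated cohorts of n = 70 for the ANOVA
  calibration; 2 000 replicates at n = 500 per group for the two-sample
  type-I calibration; 100 random instances per fit-vs-oracle check.

## Known limitations

* The apex default departs from a literal "farthest vertex" reading for the
  robustness reasons above; users wanting the literal rule set
  `apex_method="vertex"`.
* The articular circle uses the full section contour near the landmarks;
  on bones where cartilage margins are poorly captured by the mesh, the
  three-landmark fallback may be preferable.
* The metaphyseal band is defined relative to the provisional head
  diameter; pathological anatomy (e.g. severe head collapse) would need
  manual band limits.
* STL stores float32: coordinates survive STL round-trips at ~1e-4 mm for
  bone-sized objects. PLY round-trips at the same precision via the mesh
  library's writer.
* Left and right humeri are treated identically — every parameter is a
  side-symmetric distance or angle; no mirroring is performed.
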