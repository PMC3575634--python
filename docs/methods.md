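# Methods

This note records the model, its assumptions, the defaults that matter, and
the numerical choices, in the order the pipeline uses them. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. Nail model

A nail is a swept solid defined by `NailSpec`: total length, proximal and
distal diameters, a mediolateral bend (angle + station), the head-element
(CCD) angle, and a proximal cross-section shape — circular, circular with a
lateral flat, or trapezoidal.

* **Frame.** Nail-local coordinates: origin at the proximal tip, +z distal
  along the proximal segment, +x lateral (toward the flat), +y anterior.
* **Bend.** A circular-arc transition (default radius 50 mm) centered on the
  bend station, turning the distal segment medially. A sharp kink would make
  the swept surface non-manifold; the arc keeps it watertight. The
  cross-section morphs from the proximal shape to the distal circle across
  the arc.
* **Head element.** Axis + cylindrical envelope only. The axis crosses the
  nail axis at a configurable station (default 40 mm from the tip, clamped
  to the proximal segment) at the CCD angle from the *distal* axis, pointing
  medially and proximally. Thread/blade micro-geometry is out of scope:
  placement uses only the axis, and the fitness parameters are defined on
  the nail body.
* **Designs.** PFNA-II-like: 5° bend, ⌀16.5 mm proximal, lateral flat
  (default depth 1.5 mm). Legacy-PFNA comparator: 6°, ⌀17 mm, circular.
  InterTan-like: trapezoidal proximal end (defaults ⌀16.25 mm, AP depth
  15 mm, medial/lateral AP ratio 0.7), twin-screw flag set. Catalog values
  not fixed by the designs (lengths, distal diameters, bend stations, CCD
  options, the InterTan dimensions) ship as named config defaults, recorded
  in every run manifest; the pipeline default is a 170 mm × ⌀10 mm short
  nail, the size class typically chosen for the emulated population.
  Distal anterior bow of long nails is not modeled (config extension point).

Mesh construction is deterministic (bit-identical vertices for identical
spec + sampling). Cross-section girth converges to πd from below as the
circumferential sample count grows; 48 samples keep volume within 1% of the
analytic cylinder.

## 2. Femur model and frame

`FemurModel` = watertight endosteal surface + landmarks (GT apex, head
center, ≥2 shaft-axis points spanning ≥50 mm, unit anterior direction,
side flag, optional neck base). The canonical frame has origin at the GT
apex, z = total-least-squares shaft axis pointing distally, y = anterior
orthogonalized against z, x = y × z (flipped for left femora). AP and
lateral views drop the y and x coordinates respectively. Landmarks are
supplied, never detected; meshes without unit metadata are assumed mm.

The optional `neck_base` landmark (emitted by the generator) exists because
the neck-shaft angle cannot be re-estimated from the other landmarks alone:
the neck/shaft axis intersection is not recoverable from a head center and a
shaft line.

## 3. Synthetic femur generator

The generator emulates the kind of cohort the virtual-fitting literature
studies — East-Asian adult femora with pronounced anterior bowing — because
no real cohort data ship with the package.

**Geometry.** The endosteal canal is a circular tube swept along an axis
that runs straight from the neck-base level up to the apex plane and follows
a sagittal circular arc (radius = `anterior_bow_radius`, ∞ = straight)
distally. The radius profile tapers linearly from `proximal_flare_radius`
at the neck-base level to `isthmus_radius` at `isthmus_station`, constant
beyond; flat caps close the tube. Cross-sections are circular (elliptical
sections would be an extension; no section data exist to calibrate them).

Three deliberate asymmetries place the landmarks anatomically:

* the GT apex sits on the proximal cap offset **laterally** by 0.45 × flare
  radius (the trochanter overhangs the canal) and **anteriorly** by 0.35 ×
  flare radius (with an anteriorly bowed shaft the trochanter tip lies
  anterior of the distal-shaft chord; this also keeps the apex at the
  mesh's proximal extremity along the fitted axis);
* the trochanteric tube segment above the neck base is biased
  **posteriorly** by r/3 (ramped to zero at the neck base). The greater
  trochanter is a posterolateral structure; this is what makes the
  manufacturer's "anterior third" lateral-view entry rule land over the
  canal corridor, as it does in real anatomy. `cylinder_canal` (the analytic
  test scaffold) sets all three offsets to zero.

The femoral head is represented by its center landmark + radius, not merged
into the canal mesh: placement and all fitness parameters use only the
landmark and the canal surface, and a mesh boolean union is not available in
the environment.

**Population defaults** (truncated normals, ±3 sd unless noted; all
literature-typical assumptions, fully overridable and recorded per run):
femur length 430 ± 20 mm; isthmus radius 5.5 ± 0.8 mm (≥3.5); isthmus
station 180 ± 15 mm; flare radius 14 ± 1.5 mm (≥10); bow radius
900 ± 150 mm (≥500); neck-shaft angle 129 ± 5°; neck length 52 ± 5 mm;
anteversion 15 ± 5°; head radius 22 ± 1.5 mm; trochanter overhang
42 ± 4 mm (≥25). One master seed drives one `numpy` generator with a fixed
parameter draw order; joint pathologies (isthmus > flare, overhang past the
isthmus) are clipped rather than rejected so the cohort size is exact.

**What a green test establishes.** The generator reproduces the *stated*
world: circular-section tubes with exact landmarks, a single-arc bow and a
linear taper. Real endosteal canals have elliptical sections, non-constant
bow curvature, cortical thickness variation and landmark uncertainty; none
of these are emulated, so cohort-level incidences from this generator
characterize the model, not any clinical population. The generator's
parameters are, however, recoverable from its own artifacts (bow radius and
isthmus radius from the mesh, neck-shaft angle from the landmarks, each
within 2%), which is what the recovery tests check.

## 4. Placement

The guideline constraints are formalized as:

1. **Entry point**: AP position of the GT apex; lateral position at the
   anterior/middle third boundary of the trochanteric AP extent, measured
   over a thin proximal band of the mesh (1.2% of the proximodistal extent,
   ≈5 mm on an adult femur; relative so the rule scales). The point is
   projected onto the surface by ray casting.
2. **Corridor alignment**: the proximal nail segment passes through the
   entry point along the canal-corridor direction for the span the nail
   occupies. Frontally the direction is parallel to the canal axis — the
   mediolateral bend, not the insertion angle, is the design feature that
   absorbs the lateral entry offset. Sagittally it aims from the entry at
   the canal axis one nail-length down — a rigid, sagittally straight nail
   chords the anterior bow. Canal-axis estimates come from per-bin vertex
   centroids, skipping the proximal quarter of the corridor (metaphysis).
   A configurable approach-angle tilt (default 0°) is available.
3. **Depth and rotation** are the two freedoms a surgeon retains after
   choosing the entry; they are solved so the head-element axis passes
   through the femoral head center ("head element centered in the head",
   which is also what determines insertion depth). Solver: exhaustive grid,
   depth every 1 mm over a feasible window (default tip offset −20…+40 mm
   about the entry plane), rotation every 1°, refined locally to
   0.01 mm / 0.01°; ties break toward smaller depth, then smaller rotation
   in [0°, 360°). Convergence means head-center miss ≤ 1 mm; failure to
   reach 10 mm is reported as `converged=False` with the best miss, never
   an exception, and the entry point is never relaxed.

Placement is rigid and deterministic, equivariant under rigid transforms of
the femur, and permits cortical penetration by design — measuring that
conflict is the point of the analysis.

## 5. Penetration and the fitness parameters

* **Field.** The nail's side surface is sampled quasi-uniformly (default
  ≥4 samples/mm²; the cohort pipeline default is 2/mm² to keep runtimes
  down — the analytic oracles bound the discretization error at these
  densities to <0.05 mm). Depth = signed distance to the endosteal surface,
  sign from the angle-weighted pseudonormal at the closest feature
  (exact for watertight meshes); an independent ray-parity containment test
  serves as the sign oracle in the suite. Samples proximal of the entry
  plane are excluded from patch extraction — they are protrusion (D), not
  impingement. The flat tip faces are not sampled.
* **Patches.** Connected components (linkage radius 2 mm) of samples with
  depth > 0.1 mm. The threshold and linkage are explicit config values; the
  original CAD workflow used visual inspection with no numeric threshold.
  Thickness = maximum member depth (normal to the cortex — the primary
  definition; the in-plane alternative of a cut-plane measurement is not
  computed). Patch axial length = station extent along the nail.
* **Regions** are nail-relative: proximal = stations up to bend station
  + 10 mm; distal = the last quarter of the inserted length; middle =
  the remainder; boundary ties go proximal. Fixed mm-below-GT definitions
  were rejected because the canonical hot-spot loci (~60 mm and ~155 mm
  below the GT apex, and the distal tip) are emergent observations, not
  definitions. Patches are assigned by centroid station; when penetration
  is widespread a single connected patch can span a boundary and is then
  counted once, in its centroid's region.
* **Sides** are 90° sectors around the local nail axis (anterior, posterior,
  lateral, medial), 45° ties toward the mediolateral sector.
* **A–H.** A/E-thickness: max patch thickness in region. B/E-length/H: mean
  patch axial length in region (per-specimen mean over patches — the
  multi-patch semantics had to be fixed somewhere and is recorded here).
  C/F: 3-D Euclidean distance from the GT apex to the thickest patch's
  centroid (an along-axis variant is available via `distance_mode`).
  D: max(0, −z) of the proximal tip in the apex frame. G: per middle
  station, a +y ray from the nail's anterior-most surface point to the
  endosteal wall; the maximum over stations is reported together with the
  all-direction clearance. Regions without patches yield `None`, never 0.

Monotonicity caveat: raising the impingement threshold monotonically shrinks
incidence and total impinged area, but **not** necessarily the patch count —
a patch with an interior saddle splits in two as the threshold rises. The
acceptance suite asserts the monotone quantities and this caveat is why.

## 6. Cohort statistics

Fully paired design (both nails in every femur). Incidence: count and
100·count/n rounded half-up to 1 decimal; comparison by Pearson chi-square
without continuity correction when all expected counts ≥ 5, else two-sided
Fisher exact (statistic = odds ratio, which is not symmetric under arm
exchange; p is). "Repeated measures" over exactly two conditions is
interpreted as the paired t-test; Wilcoxon signed-rank is available behind a
flag. Zero-variance differences are reported explicitly (all-zero → t = 0,
p = 1; constant shift → t = ±∞, p = 0). Metric rows use region-conditional
denominators (only impinged specimens carry a thickness), except D and G
which are defined for all specimens; specimens with non-converged placements
are excluded from metric summaries and tallied separately. No multiplicity
correction is applied. Display rounding: 1 decimal for percentages,
2 decimals for mm.

## 7. Numerical choices

* Signed distance: triangle-centroid k-d tree; a 24-NN pass gives a tight
  upper bound, then an exact ball query (bound + max triangle circumradius)
  — end caps are triangulated as concentric rings precisely to keep that
  circumradius small. Closest-point classification uses Ericson's region
  algorithm; vertex/edge/face pseudonormals give the sign.
* Ray casting: Möller–Trumbore with a fixed irrational direction for
  containment parity (independent of the signed-distance path).
* Solver determinism: all grids are generated with fixed steps; tie-breaking
  is lexicographic on (miss rounded to 1e-9, depth, rotation).
* Degenerate inputs: non-watertight meshes are rejected with the open-edge
  count; anterior ∥ shaft axis is a degenerate-frame error; bow radius
  < length/π is a self-intersection error; empty depth ranges and
  on-axis patch centroids raise geometry errors.
* Scale: every default with units is either expressed relative to the
  geometry or scaled explicitly by the `.scaled(k)` helpers, which is what
  makes the scale-equivariance acceptance test exact rather than
  approximate.

## 8. Known limitations

* The synthetic world exaggerates mid/distal contact relative to published
  cadaveric studies: a single-arc bow over the whole canal plus a rigid
  nail yields deeper penetrations (several mm) than CT-derived femora show
  (~1–3 mm), and correspondingly higher incidences. Comparisons *between*
  nails within this world are meaningful; absolute magnitudes are not
  clinical estimates.
* Placement ignores reaming, fracture reduction, nail flexibility and
  surgeon variability; the entry point is never adjusted when the guideline
  position fits poorly (non-convergence is reported instead).
* Left femora are handled by the side flag only; the synthetic generator
  emits right femora.
* The head element is an axis + envelope; blade cut-out, set screws and any
  stress/strain estimates are out of scope.
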