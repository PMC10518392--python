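# Methods

## Coordinate conventions

World coordinates are millimetres on axes x = left→right, y =
posterior→anterior, z = inferior→superior. Voxel indices are 0-based; a
voxel's world position is its center (`world = origin + index·spacing`),
and a point belongs to the voxel whose center is nearest. All geometry
below is expressed in world mm; grids may be anisotropic.

## The vertebra phantom

The phantom stands in for a segmented preoperative CT of one vertebra. It
is deliberately the *simplest* geometry in which every placement rule is
meaningful:

* **Vertebral body** — an elliptic cylinder (width × depth × height,
  defaults 45 × 35 × 30 mm) with a cortical shell (default 1.5 mm) and
  superior/inferior endplate slabs of the same thickness.
* **Pedicles** — straight elliptic tubes (width × height, defaults
  9 × 12 mm) converging toward the body at a transverse angle (default
  10°, capped below 45° — strongly scoliotic geometry is out of scope).
  The tube label runs from the posterior surface, through a 6 mm
  posterior-element block, across the free span (default 12 mm along the
  axis) and through the body's posterior cortex until it meets trabecular
  bone, so the corridor is a single connected bone path.
* **Entry region** — a filled disc (default radius 3 mm) carved out of the
  posterior-most bone layer at each tube mouth. The disc voxels are
  re-labeled posterior cortical surface: they are bone, and the
  containment/breach machinery treats them as such.
* **Intensities** — constant pseudo-HU per compartment (trabecular and
  corridor 250, cortical compartments 900, air −400) plus i.i.d. Gaussian
  noise (σ = 30 HU), seeded. This gives the density-weighted trajectory
  score a signal without simulating CT physics. Labels are noise-free; the
  seed affects intensities only.

Default voxel spacing is 0.625 mm isotropic, the slice thickness of the
thin-slice CT protocols this workflow targets. The lattice is centered on
the midsagittal plane so left/right anatomy voxelises identically.

The generator emits exact truth (pedicle axis, width `W`, entry disc,
axis-ray depth to the outer anterior cortex, endplate planes). Validation:
`pedicle_width ≤ pedicle_height`, so `W` is also the minimum caliper of
the corridor cross-section — the quantity the width measurement estimates.

What the phantom does **not** model: partial-volume and beam-hardening
effects, cortical thickness variation, curved pedicles, osteoporotic
density gradients, metal artifacts, multi-vertebra context. Tests passing
on phantoms therefore demonstrate the geometric correctness of the
pipeline, not clinical performance on real CTs.

Cohort generation draws spec fields uniformly from declared ranges
(defaults: widths 7–12 mm, heights 12–15 mm, body dimensions around the
lumbar means) with per-phantom seeds derived from one master seed.

## Measurements

* **Pedicle axis** — principal direction of the label's voxel cloud,
  refined by a line fit through per-slab centroids; slabs whose voxel
  count falls below half the median are discarded (the clipped stubs at
  the body junction would drag the fit medially). Accuracy on phantoms:
  < 1° at 0°–15° convergence.
* **Width `W`** — minimum over cross-sections of the footprint's minimum
  caliper diameter. Sections (0.5 mm pitch, one-voxel-thick slabs) are
  restricted to the middle 80 % of the corridor's *free span* and must
  have wall boundary in all eight angular sectors; the caliper along
  direction u is the center extent plus the voxel-box support width along
  u (the exact caliper of the voxelised footprint). Recovery error stays
  below one voxel across widths 6–14 mm.
* **Entry candidates** — entry-disc voxel centers snapped to a grid
  anchored at the disc centroid (rounding, so mirrored discs give
  mirrored candidates). A step larger than the disc degenerates to the
  single center-nearest candidate.
* **Depth to the anterior cortex** — last bone-labeled sample along a ray
  marched at half the minimum spacing. For sizing, the *effective* depth
  of a trajectory is the minimum over the axis ray and eight rays shifted
  to the cylinder rim: the anterior surface is curved, and a tip cap sized
  to the axis ray alone would protrude where the surface recedes
  laterally.
* **Wall clearance** — minimum distance from the cylinder's lateral
  surface (samples facing the wall within 45°, restricted to the middle
  80 % of the free span) to the medial / inferior wall boundary. A wall
  boundary voxel is a pedicle voxel with a *radial* background neighbor,
  inside a 45° cone about the anatomical wall direction (medial = toward
  the midsagittal plane, inferior = −z). Distances are shifted outward by
  half the mean spacing — the gap between a boundary voxel's center and
  its face — so the value estimates distance to the label surface;
  samples outside the bone envelope contribute negatively.

## The planner

Exhaustive search over entry candidates × a transverse × sagittal angle
grid about the pedicle axis (defaults ±15°/3° × ±9°/3°, entry step 1 mm;
`COARSE_CONFIG` uses ±10°/5° × ±6°/3° and 2 mm for sweeps). Per candidate:

1. diameter: largest catalog value with `D ≤ 0.9·W` whose wall clearances
   are both ≥ the margin (default 1 mm);
2. length: largest catalog value ≤ the effective anterior depth at that
   diameter (anterior overrun is a hard constraint, zero allowed only);
3. endplate rule: no surface or axis sample may fall in an endplate label;
4. containment: the candidate's breach depth on the planning label map
   must not exceed ε (half the maximum spacing). The named margins govern
   only the medial and inferior walls; containment is what governs the
   lateral and superior walls, and enforcing it makes "feasible ⇒ grade A
   on the planning segmentation" a theorem of the implementation rather
   than a tendency.

Feasible candidates are ranked by the pullout proxy
`POF = max(BMD, 1) · π·D·L` (BMD = mean intensity over voxel centers
inside the cylinder), tie-broken by BMD, then by smaller angular deviation
from the pedicle axis, then by enumeration order (entries
lexicographically sorted). The proxy is declared, not fitted: its only
contractual property is strict monotonicity in density, diameter and
length, which is what "prefer the longest, thickest, densest-path screw"
requires. The planner is fully deterministic.

Default catalog: lengths 30–65 mm in 5 mm steps, diameters 5.0–7.5 mm in
0.5 mm steps — the granularity of commercial thoracolumbar systems.

A consequence worth knowing: with a 1 mm bilateral margin and a 5.0 mm
catalog floor, pedicles narrower than ~7 mm admit no feasible screw
(5 + 2·1 = 7 exactly); the planner reports planning-infeasible there, with
the least-infeasible constraint report attached.

## Grading

Breach depth is the maximum protrusion of the screw surface outside the
union of all bone labels (entry discs included): a screw passing from the
pedicle into the vertebral body is not a breach, only a cortical exit is.
The lateral surface and tip cap are sampled at ≤ 0.3 mm; out-of-bone
samples take their distance to the nearest bone voxel center minus half
the mean spacing (clamped at zero), the same center-to-face correction
used for clearances. The first one-radius collar at the entry is excluded
— every real screw protrudes posteriorly at its head, and that is not a
pedicle breach. Agreement with a 10×-denser sampling oracle is within
0.2 mm over randomized poses.

Grades use half-open boundaries: A iff depth ≤ ε (default half the
maximum voxel spacing — the resolution floor of the discrete surface),
B < 2 ≤ C < 4 ≤ D < 6 ≤ E. Multiplanar reslices perpendicular to the
screw axis (trilinear, pixel grid centered on the axis) support visual
audit; planes fully outside the grid are filled and flagged.

## Statistics

* `paired_t` computes `t = mean(d)/(sd(d)/√n)`, df = n−1, from the
  formula; only the t-distribution tail comes from scipy. Zero-variance
  differences raise a degenerate-test error rather than returning NaN.
* `fisher_exact_2x2` is the two-sided probability-ordering definition
  (sum of hypergeometric probabilities ≤ that of the observed table),
  computed with log-factorials and a 1e-9 relative tolerance in the
  "no more probable" comparison. It matches exact integer-arithmetic
  enumeration to < 1e-9 over every table with total ≤ 30, and the scipy
  implementation (used in tests only) to the same tolerance.
* `summarize_grades` / `compare_groups` assemble per-group × side grade
  counts, grade-A proportions, the grade-A-vs-other Fisher test, and
  per-side + pooled paired t-tests on screw length and diameter (pairing
  by screw site; unpairable cohorts flag the t-tests and keep the Fisher
  test). The published clinical tallies ship as a JSON fixture so the
  headline proportions (85.10 % vs 64.90 % grade A) and their Fisher test
  are regression-tested without clinical data.

## Problem sizes and numerical choices

The test suite and the acceptance script run on phantoms of ~4–5·10⁵
voxels; sweeps use 9–20 phantoms and the coarse search grid, which keeps
the full pipeline to a few minutes on one CPU while exercising every rule
at its clinical scale. Tolerances throughout are stated in voxels
(measurement recovery ≤ 1 voxel, oracle agreements ≤ 0.2 mm at 0.625 mm
spacing) because voxelisation, not arithmetic, is the dominant error
source. Degenerate inputs (empty labels, rays that miss bone, screws
outside the grid, all-zero tables) raise typed errors rather than
returning sentinel values.

## Known limitations

* Clearance and breach are estimated from discrete boundary/surface
  samples; both carry residual sub-half-voxel bias after the center-to-face
  correction. The planner's ≥ 1 mm margin is enforced on the estimate,
  which is conservative in the phantom's convex corridors.
* The pullout proxy is a ranking device, not a biomechanical model; it
  should not be compared across volumes with different intensity scales.
* The planner plans each side independently; rod alignment and bilateral
  symmetry are out of scope.
* Real postoperative CTs (metal artifacts, segmentation noise) have not
  been exercised; the grading module assumes a clean label map.
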