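# Methods

## Problem and approach

Attainable DVH objectives in prostate VMAT planning are governed by the
geometry of the target relative to bladder and rectum. `planmatch`
retrieves, from a database of prior cases, the case whose anatomy most
resembles a new patient's, and hands back that case's plan (isocenter,
arcs, MLC apertures) and achieved dose-volume values as a starting point
for optimization. The engine itself performs no dose calculation and no
optimization: those remain the job of the treatment planning system.
Everything below happens on contours and exported dose grids.

## Geometry representation

All geometry lives in DICOM patient coordinates (LPS), millimetres.
Structures are represented as surface *point clouds*, not meshes: both
the registration and the metric are defined on points, so a mesh would
add cost without fidelity. Contour polylines are resampled at arc-length
intervals of at most `max_point_spacing` (default 2 mm — below typical
contour slice spacing), preserving original vertices. At that density a
typical case carries 1–3 k surface points and one case-to-case
comparison runs in tens of milliseconds, keeping an interactive search
over a clinical-scale (~100-case) database comfortably fast.

Dose grids must be axis-aligned (identity `ImageOrientationPatient`);
anything else is rejected with a clear error rather than silently
resampled. Dose is sampled at points by trilinear interpolation; points
outside the grid read 0 Gy, which is the right behaviour for cropping
because exported dose grids cover the treated region.

## Isodose cropping

Bladder and rectum clouds are restricted to points receiving at least
`isodose_fraction × D_rx` (default 0.8): OAR shape far from the target
receives little dose and is irrelevant to plan transfer. The target is
never cropped. The retained set is *exactly* the per-point threshold
set `{p : D(p) ≥ f·D_rx}` — tests verify this against brute-force
evaluation and the monotonicity of retention in `f`. A crop may come
back empty (e.g. a bladder sitting entirely outside the high-dose
region); that structure is then skipped at scoring time and recorded in
the result rather than treated as an error.

## Alignment

Translation-only ICP, deliberately without rotation or scaling: the
prostate is roughly isotropic, and the payload being transferred (an
isocenter plus arc geometry) is anchored by position only.

* Initialization: `t₀ = COM(fixed) − COM(moving)`.
* Iteration: nearest fixed neighbour for every moving point (KD-tree;
  equidistant ties resolve to the lowest fixed-point index, for
  determinism), then `t ← t + mean residual`.
* Stopping: update norm < `icp_tol` (default 0.01 mm) or `icp_max_iter`
  (default 50). The mean-residual step minimizes the mean *squared*
  distance; to keep the mean distance monotonically non-increasing — the
  quantity actually being reported — a candidate step that would
  increase it is rejected and iteration stops there. On all synthetic
  cases convergence takes 1–15 iterations.

The translation maps patient points into the database frame; the
suggested isocenter is the database isocenter pulled back through the
inverse, `iso_patient = iso_db − t`.

## Similarity score

The score loops over all points of the *database* case's surfaces
(target, cropped bladder, cropped rectum), records each point's closest
distance to the corresponding patient structure after alignment, and
averages over all points (point-count weighting; an equal-per-structure
weighting is exposed as an option). Consequences worth knowing:

* The score is asymmetric (database → patient) by construction: the
  cropped database surface is the scored object.
* Correspondence is per structure — a database bladder point is never
  matched to a patient rectum, which would reward anatomically
  meaningless proximity.
* Point-to-point rather than point-to-surface distance; the induced
  error is bounded by the sampling spacing (≤ 2 mm default) and affects
  all candidates alike.
* KD-tree distances are exact, not approximate: tests assert element-wise
  equality with the O(N·M) brute force.

Ranking is ascending by score with ties broken lexicographically by
case id, so results are deterministic and permutation-invariant in the
database order. All candidates are scored; no early termination.

## DVH computation and constraint suggestions

Structures are rasterized by voxel counting: a voxel centre belongs to
the mask iff it lies inside an odd number of polygons (even-odd rule,
so donut slices exclude their hole) of the nearest contour slice, with
voxel planes matched to contour slices within half a slice spacing. No
sub-voxel partial volumes — first-order accuracy controlled by the grid
resolution (the 20 mm cube test recovers its volume to well under 5 %
on a 1 mm grid). Cumulative curves use 0.1 Gy bins with an exact
`V(0) = 100 %` anchor and a `≥` convention at bin edges.

Constraint suggestions are read off a stored curve by linear
interpolation: querying the bladder curve at {21, 42, 48, 66} Gy (the
default query doses, configurable) yields upper limits
`V(d) ≤ achieved%` usable directly as optimizer input. Doses beyond the
last bin return a 0 % limit.

## Database and plan hand-off

A database entry holds the clouds, DVH curves, the plan payload and the
index metadata (physician, institution, machine, boost flag, arc count,
prescription); CT images are never stored — the metric does not use
them. Persistence is one JSON archive with an explicit schema version:
float→decimal-string→float round-trips are exact in Python, so the
archive is lossless and two builds of the same inputs are byte-identical
(tested). Criteria filtering is a pure conjunction of equality
(categorical) and range (prescription, arc count) predicates.

Plan retargeting rewrites only patient identity, frame of reference,
fresh instance UIDs and the isocenter in every control point; MLC leaf
positions pass through as raw bytes, untouched (tested byte-exact).
Structure names are standardized through an editable tab-separated
synonym table (case-insensitive, punctuation/digit-stripped longest
prefix match; unmapped names become "other").

## Synthetic phantom

The generator emulates what matters to the engine:

* **Target**: ellipsoid (default semi-axes 25/22/20 mm) with a seeded
  real-spherical-harmonic radial perturbation of degree ≤ 4, rescaled so
  its maximum equals `deformation_amplitude` (default 3 mm) —
  organ-scale, band-limited shape variation that cannot self-intersect.
  Contours are cut on axial planes by vectorized bisection of the radial
  profile (60 iterations, so zero-deformation contours sit on the exact
  ellipsoid to < 1e-6 mm before file rounding).
* **OARs**: bladder as a sphere superior-anterior of the target, rectum
  as a posterior cylinder, positioned so their surfaces graze the
  high-dose region — some cases legitimately lose the bladder to the
  80 % crop, which exercises the skip path.
* **Dose**: analytic — prescription (default 70 Gy) inside the
  5 mm-expanded target, Gaussian falloff (σ = 8 mm) outside, quantized
  at the file writer's fixed 1e-7 Gy scaling so memory and disk agree
  exactly.
* **Plan**: two arcs (178°→182° CC and the reverse), 90 control points,
  60 leaf pairs of 5 mm, rectangular apertures fitted to the target
  extent, isocenter at the target centroid.
* **Database variation**: per-case jitter of radii (±15 %), centres and
  OAR offsets (±10 mm), and metadata sampled from small categorical
  sets, with a TSV manifest of ground truth. Near-duplicates for
  retrieval tests are built by translating a case and applying a smooth
  in-plane sinusoidal displacement normalized to a stated amplitude
  (in-plane only, so contour slices stay planar).

What the phantom does **not** emulate: realistic contouring noise and
inter-observer variability, non-convex prostate shapes, CT content,
physically computed dose (no fluence/heterogeneity structure), couch or
rotational setup differences. Passing tests therefore demonstrate the
correctness of the geometry processing, retrieval logic and file
handling — not clinical plan quality on real anatomy.

## Numerical choices and degenerate inputs

* Sizes used in the shipped test/acceptance runs: 20-case databases,
  2.5 mm dose grids, ~1–3 k points per cloud, 10 retrieval trials —
  chosen as the smallest sizes at which every behaviour of interest is
  exercised with comfortable margins.
* Dose comparisons at file precision 1e-7 Gy; contour coordinates at
  1e-6 mm (6-decimal DICOM DS formatting); MLC at 0.01 mm.
* Empty crops are flagged, skipped and reported — never errors; an
  entirely-outside-grid structure rasterizes to an empty mask with a
  warning; an empty mask is an error for `compute_dvh` (a DVH of
  nothing has no meaning).
* `crop_by_isodose` accepts fraction 0 (identity) through 1.
* Static (non-arc) beams are read with a warning; plans without beams
  or without a prescription are format errors.

## Known limitations

* Translation-only registration cannot compensate rotational anatomy
  differences; badly rotated near-matches score worse than they should.
* The score depends (weakly) on sampling density through point-count
  weighting; compare scores only across runs with the same
  `max_point_spacing`.
* Dose grids must be axis-aligned; oblique exports are rejected.
* One case = exactly one structure set + dose + plan; multi-plan
  exports must be split upstream.
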