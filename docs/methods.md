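# Methods

## Model

The package treats the bronchial tree as a finite rooted forest T embedded
in scanner coordinates (mm), densely and uniformly sampled along the
centerlines, and lung anatomy as axis-aligned voxel grids with physical
spacing. Two filtrations generate all topological descriptors:

**Depth (height) filtration.** With z pointing superior, each vertex gets
f(v) = z_max − z(v), where z_max is the top of the axis-aligned bounding box
of the (possibly rotated) tree; each edge gets the maximum of its endpoint
values, so the sublevel set X_h is the full subgraph above a horizontal
plane at depth h. Degree-0 persistence of {X_h} is computed by a single
union-find sweep with the elder rule. A finite bar (h1, h2) is a component
born at a local top h1 (an upward trajectory change of a branch) that
merges at h2 into an older component; one essential bar per connected
component is born at the component's topmost point. Upwards complexity is
the finite-bar count — the essential bar represents the whole tree, not a
trajectory change. For injective vertex values the identity
(#finite bars) + (#components) = (#local minima of f) holds and is tested.

**Alpha filtration.** For point clouds (tree nodes; surface voxel centres)
the alpha complex is the subcomplex of the Delaunay triangulation in which
each simplex appears at its critical thickening radius. Values are stored in
radius units (mm) — any squared-alpha intermediate is square-rooted — so
degree-1 bars read directly as "branches touch at r1, loop fills at r2" and
degree-2 deaths equal the circumradius of the largest empty ball in a void.
Assignment follows the standard downward propagation with Gabriel tests;
persistence in degrees 0–2 is computed by Z2 boundary-matrix reduction
processed one dimension at a time from the top down with clearing.

**Barcode metrics.** Bottleneck and Wasserstein-q distances are
optimal-matching metrics with L∞ ground cost and diagonal cost
persistence/2. Both are computed exactly: bottleneck by binary search over
the finite candidate-cost set with a bipartite feasibility matching per
step (hence any requested relative-error bound, default 1e-4, is met by
construction), Wasserstein by linear assignment on the diagonally augmented
cost matrix. Essential bars are capped at the maximum filtration value of
their construction (bounding-box depth, largest alpha radius) before
distance computations; the cap is recorded on the barcode (`fmax`) and this
choice is deliberately conservative — the essential class carries tree-size
information that would otherwise be discarded.

## Numerical choices

* **Tie-breaking** in the sublevel sweep: vertices sorted by (value,
  node_id); an edge is processed after any vertex of equal value. This makes
  the elder rule deterministic.
* **Jitter.** Voxel-grid point clouds are maximally degenerate for Delaunay
  triangulation, so a deterministic seeded jitter of magnitude 1e-6 x the
  bounding-box diagonal is always applied before triangulating; the seed is
  recorded in provenance. Point sets whose affine hull is a line or plane
  (straight or planar branches) are triangulated in their intrinsic
  dimension; the rank test uses a tolerance of 10 x the jitter magnitude so
  that jitter cannot promote a planar cloud to 3D.
* **Zero-length bars** (birth == death), which arise from the max-of-
  endpoints edge convention, carry no information and are dropped
  everywhere, including in the test oracles.
* **Degenerate inputs.** Trees with < 2 nodes return 0 for all complexity
  features; point clouds with < 4 distinct points return proximity 0 with a
  warning (no 1-cycle can form); all-identical point clouds are an error.
* **Thinning.** `branch_to_branch_proximity(max_points=...)` optionally
  thins dense centerlines by taking evenly spaced node indices. Because
  node order follows branches contiguously at exact uniform arc-length
  spacing, this is equivalent to resampling at a coarser uniform density,
  and is how the cohort pipeline bounds the Delaunay/reduction cost on
  multi-thousand-node trees (default 700 points per scan).

## Synthetic data: what it emulates, and what it does not

The generator grows dichotomous trees downward from a trachea-like trunk:
trunk length 45 mm (sd 5), geometric length decay 0.8 per generation,
branching angle 35 deg (sd 8), uniform node spacing 0.35 mm — matching the
dense centerline sampling of clinical extractions, where hundreds of
vertices separate consecutive branch points. Upward trajectory changes are
Poisson events per branch (`upward_turn_rate`); each bends a short
sub-segment (about 2.5 mm) into an ascending run, creating exactly one
local top, so the generator's event log provides an exact ground truth for
upwards complexity. Event runs are placed non-overlapping; on short
branches fewer events than drawn may fit, and only placed events are
logged.

The four cohort presets grade severity by *shrinking the visible tree*
(generations 7, 6, 5, 4 for HNS, HS, Mild, Mod) while *raising* the
per-branch turn rate (0.30, 0.40, 0.55, 0.70): disease obstructs the
peripheral airways that CT can resolve and distorts the branches that
remain. Because branch count falls faster than the turn rate rises, both
upwards complexity and tree length decrease with severity, keeping the two
descriptors strongly positively correlated across the cohort, as observed
in real populations.

The expiratory phase is derived from the inspiratory tree by a deflation
transform about the trunk root: axial (z) compression x0.85, radial
crowding of x/y toward the trunk axis x0.75, plus a deterministic
long-wavelength buckling of branch trajectories (6 mm amplitude, 25 mm
wavelength along the arc). The buckling term is essential, not cosmetic: a
pure contraction scales every alpha-barcode endpoint down by the
contraction factor and therefore *lowers* total degree-1 persistence,
whereas real deflation distorts branches toward one another. With crowding
plus buckling, expiratory branch-to-branch proximity exceeds the
inspiratory value for essentially every generated subject, and the phase
change alters the shape (not merely the scale) of the depth barcode, which
is what lets a Wasserstein-2 + MDS embedding separate the phases.

Phantoms are hollow ellipsoidal shells ("lobes") with embedded cylindrical
tubes ("airways") on a 0.7 mm isotropic grid by default, plus a synthetic
HU volume: parenchyma ~ N(−850, 30) HU with an exactly counted fraction of
voxels implanted below −950 HU, so the emphysema score has a known ground
truth. The hollow-sphere phantom uses a symmetric band shell (voxel centres
within half a spacing of the surface) so that the dominant degree-2 death
estimates the true radius without the inward bias of an eroded-ball shell.

What the synthetic data does **not** emulate: airway calibre and wall
structure, image noise and partial-volume effects, segmentation errors,
lobar anatomy, or any physiological coupling between tree shape and lung
function. Passing tests therefore demonstrate that the descriptors measure
what they claim on structures with known ground truth and that the pipeline
is deterministic and internally consistent — not that the descriptors
separate clinical populations.

## Statistical machinery

Group comparisons use the two-sided two-sample Kolmogorov–Smirnov test, one
test per group pair, reporting |KS| and raw p-values (a Holm-corrected
column is available behind a flag; the default mirrors raw pairwise
reporting). The exact null distribution is used when min(n1, n2) <= 25,
the asymptotic one otherwise. Embeddings use classical (Torgerson) metric
MDS — double-centred squared distances, top-2 eigenpairs — chosen over
stress-minimising variants for determinism; axis signs are fixed so each
axis's largest-magnitude coordinate is positive. Any rigid motion of an
embedding is considered equivalent. Pearson correlations use the standard
t-approximation for p-values.

## Design decisions taken where the design was open

* Coordinate convention: right-handed axes, third coordinate superior;
  "top" = largest z. Rotations compose about the fixed lab axes in the
  order X, then Y, then Z (right-hand rule).
* SWC is the primary tree dialect; the type column carries the airway
  generation label (airway trees do not use neuronal types) and the radius
  column is read but unused by descriptors. Multi-root files are accepted
  as forests, components treated independently; the CLI reports the joint
  vertex count (per-component counts are available via the component
  labels).
* A branch point is any node with out-degree >= 2; trifurcations count once.
* The emphysema threshold defaults to −950 HU (the conventional inspiratory
  low-attenuation cutoff) and is exposed as a flag; the score is computed
  volume-wise, not slice-wise-then-averaged (the per-slice variant would
  weight slices equally regardless of lung area).
* Height barcodes for phase comparison are computed in scanner coordinates,
  without per-phase rotation.
* Distances on height barcodes include the capped essential bar (see
  above).

## Problem sizes

Default test and acceptance runs use: 100 random trees up to 200 nodes for
the sublevel oracle; point clouds up to 25 points for reduction oracles
(hundreds of simplices); 400 sphere points for the void limit; 20 diagram
pairs of 30 bars for the bottleneck oracle; 2000 replicates (n = 100 per
group) for KS calibration; and a 4-group x 10-subject cohort with paired
phases (trees of roughly 1200–5500 nodes, proximity computed on 600-point
thinnings). These sizes were chosen so the full pipeline demonstrates every
property at desk scale.

## Known limitations

* The persistence backend is written for clarity and tested against
  brute-force oracles, not for very large complexes; clouds beyond a few
  thousand points should be thinned (the descriptors are stable under
  uniform re-sampling, and thinning density is part of provenance).
* The alpha complex relies on floating-point predicates plus jitter rather
  than exact arithmetic; near-degenerate sliver configurations could in
  principle mis-order simplices at the 1e-6 relative scale of the jitter.
* Wasserstein distances between barcodes of very different cardinality are
  dominated by diagonal costs; this is a property of the metric, not a bug,
  but it means bar-count differences can mask bar-position differences.
* The severity presets are a simulation hypothesis (smaller, more distorted
  trees with disease), not a clinical claim.
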