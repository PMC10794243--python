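# Methods

This note documents the models, defaults and design choices behind
`wmstitch`, and what the synthetic validation does and does not show.

## Problem setting and assumptions

The input is 2 or 4 digitized tissue fragments (image + binary tissue mask
+ pixel spacing) from one sectioned specimen. The method assumes:

- fragments are related to the original whole-mount by **rigid** motions
  (rotation + translation). Physical deformation during slide preparation
  and the few-µm depth offset between adjacent blocks are accepted, not
  corrected; they bound the achievable stitch quality from below.
- quartered fragments are roughly quarter-ellipses, so their two stitch
  edges lie on *adjacent* sides of the bounding box — this is enforced
  structurally (only the 4 adjacent-side classes exist).
- fragments do not share image content (no overlap to register on), so all
  costs are tissue-*shape* based; the method is staining-agnostic and
  correspondingly dependent on mask quality.
- mirrored (flipped) fragments are not searched automatically; a flip is a
  manual correction (`--flip`), matching how such cases are handled in
  practice.

Coordinates are 0-based pixel centers, `x` = column (rightward), `y` = row
(downward); rotations are counter-clockwise in that frame; bounding boxes
are half-open. A rigid transform is stored as rotation about the fragment's
mask centroid plus translation, with a `level_factor` tag; re-expressing it
at another pyramid level scales translations by the factor ratio and maps
the center through the pixel-center similarity `s(p) = (p + 0.5)·a − 0.5`.

## Stitch-edge extraction

The mask's largest connected component is hole-filled; its marching-squares
boundary is simplified (Douglas–Peucker, 1 px). For a labeled side, the
stitch edge is the contour arc between the support vertices toward the two
bounding-box corners flanking that side, choosing of the two possible arcs
the one hugging that side; adjacent labeled sides share exactly one corner
vertex. A shared corner whose interior angle exceeds 155° (near-circular
mask) raises an error that recommends a manual edge label. Edge points are
ordered along the side's sort axis (`y` for left/right, `x` for
top/bottom), which makes landmark correspondence between paired edges a
pure index match after both are sorted along the shared axis — no reversal
search, fully deterministic.

Edges are extracted once at the native working resolution and *rescaled*
per pyramid level rather than re-detected from each downsampled mask:
corner support on a ~26 px coarse mask is unreliable, while rescaled
coordinates stay consistent across levels by construction. Finer levels
still refine the stitch because mutation bounds shrink and the cost is
evaluated in that level's (smaller) pixels. Edges are kept corner-to-corner
without trimming ragged tissue.

## Geometric edge classifier

Each candidate class's arcs are extracted exactly as above and scored by
the maximum perpendicular deviation of the arc from its chord, normalized
by the mask bounding-box diagonal (length-weighted mean over the class's
arcs; lower is straighter). Classes containing an arc whose chord spans
less than 30% of its bounding-box side are rejected — a sectioning cut
crosses most of the fragment, and without this guard a tiny sliver arc near
a corner (deviation ≈ 0) can win the average. Confidence is the relative
margin over the runner-up class, `(s₂ − s₁)/(s₂ + s₁)`, clipped to [0, 1];
below 0.5 the pipeline logs a recommendation to label the edges manually.
The score is a pure function of the mask, so predictions are deterministic
and exactly equivariant under 90° rotations and mirror flips. On synthetic
quartered cases (±20° perturbations) the classifier labels 200/200
fragments correctly in the test suite; on oddly shaped real fragments the
manual override is the intended fallback. An optional learned backend can
be slotted in through the same `EdgeLabelPair` interface
(`prepare_classifier_input` provides the canonical 16 µm/px, white-padded,
512×512 input geometry); none is bundled.

## Configuration search

One fragment (the first) is anchored at rotation state 0; each remaining
quadrant takes one of four 90° rotation states, and its rotated edge label
determines its slot (UL/UR/LL/LR) — 4³ = 64 candidates, of which at most
3! = 6 can place the fragments in distinct slots, which is why at most six
feasible reconstructions are ever suggested. Feasibility = single adjacency
loop + pairwise overlap ≤ 20%, where overlap is |A ∩ B| / min(|A|, |B|)
(the smaller-fragment denominator is symmetric and scale-robust; the
threshold is applied to adjacent pairs).

The initial placement walks the adjacency cycle outward from the anchor and
rigidly aligns each fragment's stitch edge to its already-placed partner
edge *in order*: midpoints coincide and the least-squares rotation over the
ordered landmarks is applied, clamped to ±45° so a candidate cannot drift
into a neighbouring rotation state. A translation-only initialization was
tried first and discarded: with ±20° preparation rotations it leaves
wedge-shaped overlaps large enough that the correct candidate can fail the
20% overlap filter. Candidates are ranked by the mean Euclidean landmark
distance between paired edges (same formula as the GA cost) at the
coarsest level; a mean-squared variant is available as a switch
(`squared=True`), ties break on smaller overlap, then enumeration order.

## Genetic-algorithm refinement

- Cost: `C_pair = (1/k) Σ ‖p_{f1,i} − p_{f2,i}‖₂`, `C_total` = mean over
  the `j` adjacent pairs; `k = 32` landmarks per edge by default (ten are
  enough for *evaluation*, but a denser set stabilizes optimization on
  curved edges).
- Population 40 = 2 elite parents + 38 mutants; each mutant perturbs
  *every* free parameter (rotation, tx, ty per non-anchor fragment) by an
  independent uniform draw within the level's mutation bounds. Parent
  selection is rank truncation; there is no crossover — variants are
  bounded variations of the parents.
- A level ends after 50 generations without improvement of the best cost,
  or at 200 generations. Elitism makes the best-cost trace non-increasing.
- Resolution schedule: descending factors {20, 6.66, 2.22, 1} relative to
  the finest working level, preserving the canonical 2560:853:284:128
  whole-slide ratios (with native 0.25 µm/px scans the absolute factors
  apply unchanged and the finest level works at 32 µm/px). The best
  solution is rescaled and propagated between levels; landmark sets are
  fixed per level and move rigidly with their fragments.
- Mutation bounds: ±3° rotation and ±3% of the coarse canvas diagonal at
  the coarsest level, both halved at each finer level (translations
  expressed in that level's pixels). Coarse levels can therefore absorb the
  full ±20° preparation rotation over tens of generations, while the finest
  level makes sub-pixel adjustments.
- Determinism: one master seed fans out to per-solution GA seeds via
  `numpy.random.SeedSequence`; identical inputs + seed reproduce identical
  transforms, reports and rasters byte-for-byte.

## Full-resolution reconstruction

Transforms are applied per target tile by inverse mapping (bilinear for
images, nearest for masks, white background matching H&E slides); pure
integer translations take an exact slicing path, so an unrotated case
recomposes bit-exactly. The canvas adds a 2% diagonal margin. Fragments are
composited in configuration-cycle order: new pixels are copied, overlap
pixels blended with `α = d_B/(d_A + d_B)` (0.5 where both distances
vanish), `d_A`/`d_B` being Euclidean distances to each side's exclusive
tissue. The exact functional form of α is this package's choice; it
satisfies the stated requirement (proportional to proximity) and is convex,
continuous across tile boundaries, and equal to 0.5 on the medial line.
Overlaps of more than two fragments blend pairwise in cycle order with a
warning. Distance transforms are computed once per fragment addition at a
bounded working resolution (≤ 4096 px long side) and upsampled — exact
native-resolution distance transforms would defeat the tile-memory bound
for gigapixel canvases, and the upsampling error is sub-pixel. Output is a
tiled (deflate) multi-level TIFF with halving levels and resolution
metadata, plus a ≤ 2048 px PNG preview; a failed write removes the partial
file. At desk scale the assembled canvas is held in memory; the per-tile
transform keeps the working set bounded for large canvases.

## Evaluation

Auto-landmark mode resamples each stitched edge at ten evenly spaced
arclength fractions and reports the index-paired distances in mm (median
and IQR), plus a relative error = median / mean(WMS width, height) × 100.
The WMS size is the placed tissue bounding box (not the canvas). Because
the points are chosen on the result itself this mode is an approximation
and is labeled as such. Ground-truth mode maps each recorded landmark pair
through the estimated placements; it is exact, invariant to a global rigid
motion of the reconstruction, and flagged `not_comparable` when the chosen
arrangement differs from the true one. Dice/mutual-information metrics are
deliberately out of scope: adjacent fragments share no structures to
overlap. Errors are evaluated at the finest working level and converted to
mm via the pixel spacing.

## Synthetic data generator

`generate_wms` draws an ellipse with low-order radial harmonics (area
fraction 0.25–0.75 of the canvas, single connected component) and fills it
with an eosin-pink base, smoothed Gaussian intensity noise and scattered
dark blobs on a white background — enough structure to make misalignment,
blending and landmarks visually and numerically checkable; histological
realism is irrelevant to a shape-based method. Blob fields saturate through
`tanh` rather than clipping so the texture stays C¹-smooth and a double
bilinear warp changes interior intensities by ≤ 2/255 (the round-trip
tolerance asserted in tests; checked on a slightly eroded placed mask,
since pixels whose interpolation support straddles the tissue border mix in
background). `cut_wms` cuts along quadratic Béziers whose control point is
jittered sideways by `curviness` × mask diameter (default 0.03 — slightly
curved, like real sectioning cuts); fragments exactly partition the mask,
and ≥ 10 landmark pairs per cut are recorded as midpoints between
4-adjacent pixels of the two sides, i.e. exactly on the cut. A failed cut
(near-empty fragment, too few landmarks) is rejittered up to 5 times.
`perturb_case` applies per-fragment rotation (uniform in ±20° by default),
integer shifts (±5% of the canvas by default) and optional horizontal flips
(default probability 0 — flips are a manual-correction scenario), cropping
each fragment to its own canvas and recording the exact inverse affine.
Defaults: 512×512 px canvas at 16 µm/px, so a whole case stitches in
seconds while mm-scale error reporting stays meaningful; the acceptance
study uses 10 such cases for recovery and 20 for the parsimony count.

What the synthetic tests do **not** show: robustness to non-rigid
deformation, stain variation, scanner noise, imperfect tissue masks, or the
shape diversity of real specimens (e.g. pancreas fragments, where edge
labels are expected to come from the manual override). Synthetic recovery
errors (~0.01 mm) are accordingly much smaller than what real tissue
allows, where rigid transforms cannot fully interlock deformed fragments.

## Numerical notes and limitations

- Landmark ordering uses a stable sort along the shared axis; strictly
  monotone edge polylines (ties dropped) guarantee a unique order.
- Degenerate stitch edges (< 4 px at the working level) mark a candidate
  infeasible rather than producing spurious alignments; evaluation skips
  degenerate pairs with a warning.
- Zero feasible candidates raises an error recommending `--edges`/`--flip`
  overrides (exit code 2 from the CLI; 3 for I/O errors).
- Fragment counts other than 2 and 4 are rejected; larger cases can be
  stitched iteratively in batches of 2/4 by the user.
- The GA cost is non-convex across candidates; this is handled by
  propagating the top-N candidates rather than trusting rank 1, at a
  roughly linear cost in N.
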