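# Methods

This note documents the models, parameters and design choices behind
`leafpheno`, in the order the pipeline runs them.

## Leaf model and component algebra

A detached lettuce leaf is described by six aligned binary masks. Four
are annotated — blade `BD` (the whole leaf, petiole included), mid-rib
`MR` (petiole + first-order vein, base to apex), second-order veins
`VS`, laminas `LM` — and two are derived set-algebraically: venation
`VV = MR ∪ VS` and marginal zone `MZ = BD − VV − LM`. Loading treats any
8-bit pixel above 127 as foreground (files that only contain 0/1 are
accepted as-is); masks of one leaf must share dimensions. Derived masks
are flagged `derived` so provenance survives a save/load round trip.

Area bookkeeping uses eleven indicators: five component-to-blade ratios
(`X_A_Ratio = 100·|X|/|BD|`), three within-venation ratios
(`MR_VS_A_Ratio`, `MR_VV_A_Ratio`, `VS_VV_A_Ratio`), and three
"excess-area" overlap indicators

    EVA_X_Y_2_Z = 100 · (|X| + |Y| − |Z|) / |Z|,

which is 0 exactly when X and Y partition Z and grows with the overlap
of X and Y inside Z. The excess-over-reference form is one of several
plausible readings of an overlap score; it is isolated in a single
function (`components.excess_area`) so it can be swapped without
touching anything else. An indicator whose denominator component is
empty is *undefined* (`None`, empty CSV cell) — never coerced to 0,
which would fake a measurement.

## Normalization

Leaves arrive at arbitrary pose and scale; all shape traits are measured
in a canonical "size-free" frame.

* **Upright rotation.** The minimum-area oriented bounding box (OBB) of
  `MR` is computed over the convex hull of its foreground pixels
  (rotating-calipers contract; pixels count as unit squares, so a single
  pixel yields half-extents 0.5 × 0.5). The box is split at its midline
  perpendicular to the long axis; because the petiole is always markedly
  thicker than the first-order vein, the half with more `MR` pixels is
  the petiole half. The rotation aligns the petiole→apex centroid line
  with the vertical axis, petiole down. The OBB is used *only* for the
  half split; the rotation angle comes from the centroid line, which
  tracks the curved mid-rib better than the box axis.
* **Tie-break.** If both halves hold exactly equal pixel counts the half
  whose centroid lies lower in the image is taken as the petiole
  (petioles hang down in the acquisition setup) and a warning is logged.
  If all `MR` pixels fall in one half, the apex is the `MR` pixel
  farthest from the petiole centroid.
* **Scaling.** After rotation the leaf is scaled uniformly so the
  blade's horizontal extent equals `normalized_width` (default 500 px, a
  balance of resolution and cost). "Leaf width" is the horizontal extent
  of `BD` *after* the upright rotation — the normalized leaves share a
  width and differ in length. The reported scaling factor is
  post-rotation width / 500; rotation of a rigid shape does not change
  its intrinsic width beyond rasterization, so the factor is a
  pose-invariant size proxy (the rotation-sweep test bounds its per-leaf
  std at 0.03, measured values are ~2×10⁻³).
* **Interpolation.** Nearest-neighbour for masks (labels preserved, area
  drift within rasterization tolerance), bilinear for RGB. Output is
  cropped to the blade bounding box plus a 10-px margin.
* **Canonical flip.** The back (abaxial) photograph of a leaf is the
  mirror image of its positive (adaxial) photograph; back leaves are
  reflected about the vertical axis so both faces share handedness. The
  criterion is the recorded orientation label — nothing in a single
  image reveals its face — and the flip can be disabled (`--no-flip`).

## Vein architecture

* **Skeletons.** Components are thinned with a topology-preserving
  skeletonization (1-px, connectivity preserved). Node classification
  uses the crossing number (0→1 transitions around the 8-neighbour
  ring): endpoints have crossing number 1, branch points ≥ 3. Plain
  neighbour counting overcounts nodes at T-junctions. Arc lengths count
  diagonal steps as √2; the mid-rib's main path (longest
  endpoint-to-endpoint path, Dijkstra on the pixel graph) is smoothed
  with a 7-tap moving average before measuring arc length, since raw
  8-connected chains overestimate length by a few percent, and is
  extended along its end tangents to the mask boundary so arc positions
  start at the true leaf base.
* **Region partition.** The blade cut by a skeleton uses 4-connected
  labelling (the topological dual of 8-connected curves), with skeleton
  end-segments prolonged to the blade border — a thinned skeleton stops
  half a stroke-width short of the boundary and would otherwise let
  neighbouring regions leak around the vein tips.
* **Left/right split.** The mid-rib main path, linearly extrapolated
  from both ends, gives one divider column per row (the leaf is upright
  here); pixels strictly left/right of it form the two sides, divider
  pixels belong to neither, so left ∪ right ∪ divider is an exact
  partition.
* **Petiole.** `MR` is dilated by the adjacency radius (default 5 px in
  normalized space, configurable); laminas touching the dilation are
  adjacent. Each adjacent lamina is projected to the arc position of the
  mid-rib pixel nearest to it (candidates tie within 1 px — pixel
  quantization); the smallest projection s\* splits the mid-rib:
  `PE_L = s*`, `AP_L = MR_L − s*`. No adjacent lamina ⇒ `PE_L`
  undefined, whole mid-rib reported as first-order vein, warning logged.
* **Attachment points and vein angles.** Lamina contours (sub-pixel
  boundary tracing) are simplified with Douglas–Peucker at tolerance
  5 px — the simplified polygon is a subset of the contour points and
  deviates at most the tolerance. The attachment point is chosen
  lexicographically: minimal distance to the mid-rib skeleton, ties
  broken by distance to the leaf base. The tie window equals the DP
  tolerance: simplification can displace the corner vertex by up to
  that much, and a 1-px window was observed to skip the true base-side
  corner on curved leaves and latch onto the lamina's apex-side corner
  instead. The vein angle is the interior angle of the two polygon
  edges incident to the attachment vertex, in (0, 180]; zero-length
  edges are skipped to the next distinct vertex.
* **Screening.** Laminas under 25 px² (annotation slivers, the main
  source of counting errors) are dropped before counting; the threshold
  is configurable and logged. Mid-rib skeletons with more than two
  endpoints fall back to the longest end-to-end path with a logged
  warning.
* **Mid-rib reconstruction (validation only).** Left and right laminas
  (plus same-side veins) are morphologically closed into two blocks; the
  corridor between them, extended across rows where the remaining blade
  is no wider than a petiole, reconstructs the mid-rib. Its IoU against
  the annotated `MR` (≥ 0.6 on clean synthetic leaves) is a consistency
  check of the lamina representation, not a pipeline stage.

## Traits

30 geometry + 20 venation + 216 colour = 266 traits per leaf. The
geometry and venation registries contain every symbol with an
established meaning in this workflow (`BD_L`, `PE_L`, `LM_Ave_ANG`, the
8 + 3 area indicators, `BD_PE_PX`, `LM1_A_LT/RT`, …) topped up with
standard morphometrics (perimeter, convex-hull areas, solidity, aspect
ratio, per-side areas, skeleton node counts, vein density =
venation-skeleton length / blade area) to the stated counts; the
registry in `traits.py` is the single place to swap entries.

Colour conventions (8-bit input): RGB raw 0–255; HSV with hue mapped to
[0, 360); **LAB** is the 8-bit-quantized L\*a\*b\* (L·255/100, a+128,
b+128, clipped to [0, 255]) while **CIELab** is the floating-point CIE
L\*a\*b\* (L ∈ [0, 100]) — both names appear in the field's usage
without distinction, so the two common encodings are emitted under the
two names; LUV is CIE L\*u\*v\* under D65; YCrCb follows ITU-R BT.601
with channels ordered (Y, Cr, Cb). Standard deviation is the population
statistic (divisor N). All 36 values of an empty component are
undefined.

## Cohort statistics

* Agreement: R² = 1 − SS_res/SS_tot with the manual values as reference,
  MAE, MAPE; R² undefined for zero-variance manual data, MAPE for zero
  manual values.
* Positive–back difference: `PB_X = 100·(X_pos − X_back)/X_pos`, signed
  so a trait larger on the back face is negative. Relative-to-positive
  is a convention choice (relative to back or to the mean are equally
  defensible); it is isolated in one function.
* Feature importance: a single CART classification tree (Gini impurity,
  unlimited depth, fixed seed), importances rescaled to percent.
* PCA: features are z-scored first — the trait groups mix pixels,
  degrees and colour units — and constant columns dropped with a
  warning; top 10 components per feature set (GEO/VEN/CLR/COM).
* Clustering: agglomerative with Euclidean distance, Ward linkage by
  default (single/complete/average available), dendrogram cut at k = 4.
  No multiple-testing correction is applied anywhere (none of the
  analyses is a hypothesis-test family).

## Synthetic leaves

The generator renders the study conditions end to end: an ovate blade
(perpendicular offsets from the mid-rib with a beta-like half-width
profile, widest below the middle), a mid-rib bowed as a half sine wave
whose petiole segment is at least twice the vein width, second-order
veins attached at evenly spaced arc positions (fractions 0.10–0.78 of
the blade span) at user-given angles, laminas as the fields between
consecutive veins (classified by exact half-plane tests against the
vein lines), a marginal band (blade minus its erosion, default 12 px),
and a flat-colour rendering with seeded Gaussian noise (sd 3/255 per
channel). Canvas padding is 10 % of the blade length on every side.

Ground truth describes the *emitted* rasters: areas are mask pixel
counts; each lamina's attachment is its rendered corner pixel (closest
to the exact centerline polyline, ties toward the base) and arc
positions are measured from the rendered base tip, including the round
cap of the petiole band. Vein angles are the exact input parameters.
Within a side, angle lists must be non-increasing base→apex — straight
veins would otherwise cross inside the blade and merge laminas; the
random-parameter helper draws angles i.i.d. uniform and sorts them,
which preserves the marginal distribution. Configurations whose veins
are too crowded, or whose laminas come out empty or fragmented, raise
`GenerationError` rather than emitting inconsistent truth.

Default parameter ranges (blade 480–700 × 300–460 px, petiole 80–160 ×
14–20 px, veins 4–6 px wide, 3–5 per side, curvature 0.01–0.07 of blade
length) give leaves whose proportions match the detached-lettuce
imagery the pipeline targets at its working resolution.

What the generator does **not** emulate: photographic texture and
lighting, leaf folds, twisted veins, multiple main veins, third-order
venation, segmentation errors (masks are clean by construction) and the
small-area lamina fragments real annotation produces. Passing tests
therefore demonstrate the correctness of the measurement pipeline on
specification-conforming leaves, not robustness to segmentation noise.

## Problem sizes and numerical notes

The test suite and the acceptance script run synthetic cohorts of 20–40
leaves (the rotation-sweep check uses 20 leaves × 7 angles; the regime
separation check 2 × 20 leaves end to end), sizes at which every
documented bound is exercised comfortably on a single CPU. Recovery
tolerances — lamina counts exact, petiole length within 5 px, vein-angle
MAE within 5°, attachment vertices within a few pixels — reflect the
compounded rasterization, thinning and polygon-simplification error
budget; measured values on clean synthetic leaves are typically half the
bounds or better. All randomness is seeded; identical inputs give
bit-identical outputs, including the trait CSV.
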