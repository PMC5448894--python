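# Methods

This note records the models, numerical choices and open design
decisions behind `filatrace`, and what the synthetic benchmark does and
does not establish.

## Image model and preprocessing

The working object is a calibrated 2-D intensity field (row-major,
origin top-left, pixel centres at integer coordinates, pixel size in
µm). Orientation angles are measured from the horizontal (column) axis,
counter-clockwise, and treated axially (mod 180°).

Intensities are min-max normalised to [0, 1] before any processing, so
every detection threshold lives on a fixed scale. Two error sources are
then reduced in order:

1. **ROF total-variation denoising** (Chambolle's projection algorithm,
   via scikit-image), weight λ, default 0.1. λ = 0 is the identity; a
   constant image is a fixed point; the output's total variation never
   exceeds the input's. The choice of the variational model is the
   canonical one; λ is deliberately config-exposed because no value is
   canonical for all detectors and magnifications.
2. **White top-hat** with a flat disk, radius default 15 px — an order
   of magnitude above the 1–3 px filament half-width at typical confocal
   magnification. The top-hat is anti-extensive, non-negative and
   (numerically) idempotent; an additive intensity plane changes the
   output only by the plane's variation across one disk.

*Caveat*: Chambolle's scheme uses one-sided finite differences and is
therefore not exactly equivariant under 90° rotations; the detection
stage itself (Laplacian, quantile, bilinear profiles) is grid-exact
equivariant, which is what the invariance test pins down.

## Ridge detection (predictor–corrector)

- **Predictor.** Ridge strength is −Δu with the 4-neighbour digital
  Laplacian (8-neighbour switchable), replicate-padded. The threshold is
  the *q*-quantile of the positive strengths (q default 0.5; quantiles
  are invariant to intensity scaling). The comparison is ≥, so a
  constant-strength crest plateau survives when the quantile lands
  exactly on it. A high default (0.9) was rejected: on clean or sparse
  images the positive-strength population is the ridge band itself, and
  a 0.9 quantile discards 70 % of the crest. With q = 0.5 the corrector
  carries the precision burden, which measurement confirms (see below).
- **Corrector.** For every 8-adjacent pair of candidate pixels, the
  perpendicular profile u(−h), u(0), u(+h) is sampled (bilinear
  interpolation) at m = 5 points along the segment, h = 1.5 px; the
  segment is accepted when the mean second difference is ≤ −κ
  (κ default 0.2 on normalised intensities).
- **Redundancy reduction.** Candidates are processed from most to least
  concave (ties broken lexicographically by pixel coordinates, so the
  result is deterministic). An accepted segment *represents* every
  candidate pixel whose perpendicular distance to it is ≤ h within the
  segment's extent. A candidate is skipped when both of its pixels are
  represented *by the same growing chain* — a segment joining two
  distinct chains is never redundant. Representing only endpoint pixels
  would accept one segment per candidate pixel (triple-tracing every
  ridge); skipping joins would leave a 1-px gap wherever two chains
  meet.
- **Subpixel refinement.** Each endpoint moves perpendicular to its
  segment onto the parabolic maximum of its 3-point profile, clamped to
  [−h, h]; the shift is computed once per pixel (by the first, most
  concave accepting segment) so consecutive segments share endpoints
  exactly.

## Feature graph and trail decomposition

Segment endpoints within 0.75 px are fused (node = centroid). The raw
graph then carries pixel-scale jitter, which three cleanup moves remove
before measurement; all are consequences of the ridge's finite width and
of the single-filament model, and all are config-exposed:

- **Tip linking/fusion** (≤ 3 px): noise locally weakens the ridge and
  breaks a chain by a pixel or two; tips of different components are
  fused (≤ 2.1 px) or bridged.
- **Stub pruning** (< 6 px ≈ the ridge's own width): a walk from a chain
  tip that hits a branching point or a bend < 135° within less than the
  ridge width is an artifact, not a filament; isolated components are
  never pruned this way.
- **Chain straightening**: maximal degree-2 chains are simplified by
  Douglas–Peucker with 1.5 px perpendicular tolerance, yielding maximal
  straight parts. An enclosed-angle criterion (e.g. "collapse nodes
  straighter than 170°") was rejected: on 1-px edges a 0.5 px
  perpendicular jitter is a 27° angle error, so angle thresholds either
  collapse nothing or everything. Surviving degree-2 nodes are genuine
  bends; degree ≥ 3 nodes are branching points.

**Decomposition.** Edges are partitioned into trails — walks using each
edge exactly once — such that no interior enclosed angle is < 135°
(the single-filament curvature bound) and, lexicographically, (1) the
number of trails, (2) the total turning Σ(180° − enclosed), (3) the
largest single turn, (4) edge order, are minimal. Minimising turning
alone is degenerate (singleton trails have zero turning), hence the
trail-count-first objective. Because the objective decomposes over
per-node pairings of incident edge ends, each node is solved
independently by exhaustive matching (degrees are small); this is
globally optimal whenever the induced walks are open. If a pairing
closes a cycle, the component is re-solved by exhaustive enumeration
over all per-node matchings with best-cut evaluation (components ≤ 24
edges / ≤ 2·10⁵ combinations), else each cycle is cut greedily at its
sharpest bend. Tests verify agreement with an independent
exhaustive enumeration of *all* trail partitions on random graphs.

**Decomposition cleanup.** After a first decomposition, two further
moves run until stable (≤ 3 iterations): edges of a shorter trail lying
within 3 px of a strictly longer trail are absorbed (double-traces of
one ridge); trails below 2 px — a pair of subpixel points inside one
cross-section, beneath the detector's resolution — are dropped; and
trail ends of different components within 8 px are bridged when every
virtual bend of the bridge respects the 135° bound (end directions are
averaged over the last 4 px, because the final edge alone is angularly
noisy). The user-facing `--min-length` filter (µm) remains off by
default.

## Orientation statistics

Straight parts (trail edges) contribute their axial angle weighted by
length. Angles are doubled; the weighted resultant gives R ∈ [0, 1], the
preferred axis µ = atan2(S, C)/2 ∈ [0°, 180°), and the von Mises
concentration κ = A₁⁻¹(R) by the standard three-branch (Best–Fisher
style) approximation, capped at κ = 500 for R → 1. When the single-mode
assumption fails (two balanced perpendicular families), R → 0 and the
fit approaches the uniform density. The **orientation dispersion** is
the linear map d = (1 − R) · 0.5 rad = (1 − R) · 28.6479°, chosen
because it reproduces both documented endpoints exactly (0° for one
preferred orientation, 28.65° for uniformly distributed oriented
length) and is monotone in R; other maps with the same endpoints exist,
so dispersion values between the endpoints are estimator-specific. The
histogram uses 36 bins of 5° by default; its polar rendering is
mirrored at the origin, with the fitted density drawn on the half
circle.

## Morphometry

Area = foreground pixel count × (pixel size)²; perimeter = length of the
marching-squares iso-contour at level 0.5, simplified by Douglas–Peucker
with 1 px tolerance before measuring — the raw staircase contour
overestimates a digitized circle's perimeter by ~5 % (and boundary-pixel
counting by up to ~27 %), which would depress the form factor 4πA/P²
systematically; after simplification digitized circles of r = 30–80 px
score 0.986–0.993. Real corners at cell scale deviate far more than 1 px
and are preserved. Cells are 8-connected components; components under
50 px² are dropped as debris; masks with ≠ 1 component are rejected by
the single-cell measurement (label and split first).

## Synthetic scenes: what they emulate, and what not

A scene is a set of polylines with Gaussian cross-section (amplitude 1,
σ = 1.5 px) over an intensity plane, plus additive Gaussian read-out
noise. Distances to the polyline are computed exactly per pixel within a
±4σ band — correctness over speed. The benchmark generator places 1–10
filaments of 30–90 px (≥ 20 px), pairwise spacing ≥ 10 px, per-bend
turning ≤ 10°, noise σ = 0.15 (SNR ≈ 6.7, "moderate"); density is a
parameter, not a hard limit, because reconstruction degrades gradually
as filaments crowd. Not emulated: PSF convolution, Poisson photon
statistics, photobleaching, out-of-focus light, 3-D structure, filament
crossings at shallow angles, and intensity variation along a filament.
A green recovery test therefore establishes correctness of the tracing
logic under the stated image model, not performance on real confocal
data; parameters will need re-tuning per microscope.

Measured on this stated world (40 scenes, two disjoint seed sets): exact
filament-count recovery in 39/40 scenes, mean absolute total-length
error ≈ 2.5 %.

## Degenerate inputs and ties

Constant images yield zero detections and a valid all-missing metrics
row. Zero total part length makes orientation statistics undefined (an
error by contract). µ is reported as 0° when the resultant vanishes
(arbitrary by symmetry). All orderings that affect output (candidate
acceptance, pairing ties, trail ordering) are broken deterministically,
so fixed input and configuration give byte-identical CSV rows.
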