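# Methods

## The measurement

Slender mesenchymal-like cells in brightfield frames expose long,
nearly straight boundary runs; cobblestone epithelial cells and bright
detached floating cells expose only short or curved ones. The pipeline
therefore measures elongation as the set of straight boundary lines of
at least 20 px: their count approximates the number of slender cells in
view, and the summed per-cell line length approximates cell length.
This is an optical proxy, not a segmentation: a cell is represented by
the straight parts of its boundary, so reported lengths track but do
not equal geometric cell lengths (see "known limitations").

## Pipeline stages and parameters

### Preprocessing

* **Gray conversion.** BT.601 luminance weights (0.299, 0.587, 0.114);
  equal-channel pixels are invariant to the choice. Intensities are
  normalized by bit depth (`/255` or `/65535`) by default so the cube
  stretch behaves identically across the frames of a time series;
  per-image min-max normalization is an opt-in (`normalize="minmax"`)
  for drifting exposure.
* **Median filter**, default 3×3 — the smallest window that deletes
  isolated salt-and-pepper pixels while preserving thin boundaries.
  Borders are edge-replicated; zero padding would create a dark frame
  margin and spawn spurious edges.
* **Cube contrast stretch** `F = G³`. Strictly monotone on (0, 1) with
  fixed points 0 and 1 and `F ≤ G` everywhere: dark cytoplasm is pushed
  further down, bright medium stays near 1, so boundary gradients grow.
* **Canny edges**, default `sigma = 1.5` px. Hysteresis thresholds are
  derived per image from the gradient-magnitude distribution as
  `high = max(0.2 · max_gradient, 0.05)` and `low = 0.4 · high`.
  The fraction-of-maximum term makes the edge map invariant to global
  affine intensity rescaling; the absolute floor matters for frames
  with little boundary content, where quantile- or maximum-based
  thresholds alone would drop into the gradient mass produced by
  illumination ramps and 8-bit quantization staircases (≤ ~0.015 on
  this scale, versus ~0.5 for blurred cell boundaries) and mark long
  spurious edges along iso-illumination lines. Explicit `low`/`high`
  values are interpreted as quantile fractions of the gradient
  distribution instead.

### Hough line detection

Coordinates are 0-based with the origin at the top-left corner,
x = column, y = row; θ ∈ [0, π) so each undirected line is unique, and
ρ = x·cosθ + y·sinθ in pixels. Discretization defaults to 1° × 1 px;
the ρ axis spans ±⌈image diagonal⌉, so every vote lands in the array
and total votes always equal (#edge pixels) × (#θ bins). The nearest ρ
bin is chosen by rounding ρ/step (round-half-even); rounding after
adding the bin offset was observed to flip bins through floating-point
carries and is deliberately avoided.

Peaks are local maxima with at least `min_votes` votes under
non-maximum suppression (default window 11×11 bins, wrapping θ at π
with ρ negated); ties break toward lower θ then lower ρ bins for
determinism. `min_votes` defaults to 20, the line-length floor — a
straight run shorter than the floor cannot reach it.

Accumulator peaks are infinite lines, but per-cell lengths need finite
segments, so edge pixels within `lateral_tol` (default 2 px) of a peak
line are projected onto it, sorted, and chained into maximal runs with
internal gaps ≤ `max_gap` (default 3 px). Runs of Euclidean length
≥ 20 px are emitted. The floor is applied to Euclidean segment length
(mirrored by `min_votes` on the accumulator side); it is what rejects
rounded floating cells — a disc of radius 8 px admits no 20 px run
within the lateral tolerance.

### Post-processing

Two artifact classes are corrected, in this order:

1. **Duplicate removal.** Segments closer than 15 px with an included
   angle under 20° (both strictly) mark the same cell; the shorter is
   removed. Distance is the minimal point-pair distance between the two
   closed segments (infinite-line distance would vanish for any
   non-parallel pair and void the rule); the angle is the acute angle
   between undirected directions. With more than two mutual conflicts
   the resolution is greedy by descending length — accept a segment iff
   it conflicts with no already-accepted one, ties broken by
   (θ, ρ, x₁, y₁). This equals the lexicographically length-favoring
   maximal conflict-free set (verified against exhaustive enumeration
   in the tests), is idempotent, and honors "keep the longer".
2. **Fragment merging.** Segments that intersect or have endpoints
   within `join_tol` (default 5 px — kept below the 15 px duplicate
   radius so true neighbors are not re-merged) form connected
   components, each becoming one piecewise line whose length is the sum
   of member lengths. Members are ordered along the component's
   principal axis; the terminal pair with the largest separation gives
   the start/end points, start being the smaller (y, then x).

### Quantification

Bins over reported lengths are half-open — [20, 25), [25, 30),
[30, 40), [40, ∞) — so every length falls in exactly one bin and the
percentages sum to 100. SD is the sample standard deviation (ddof = 1),
matching the mean ± SD convention for small replicate counts. An image
with no lines reports n = 0 and NaN mean rather than an error.
Group-level significance testing is deliberately exported, not
computed: the long-format table (one summary row plus one row per line,
keyed by group/day/image) feeds any standard ANOVA tooling.

## The synthetic generator

Scenes emulate what matters to this detector: adherent cells darker
than the medium (cells 0.45 vs background 0.75), bright rounded
floating cells (0.95), a multiplicative linear illumination ramp
(default amplitude 0.1), Gaussian blur (σ = 1 px) and salt-and-pepper
noise (rate 0.002), in that order, quantized to 8 bits. Elongated cells
are capsules around a straight centerline (length 50–70 px, aspect
ratio 5–7 by default, so widths stay under the 15 px duplicate radius
and one side line survives deduplication per cell); cobblestone cells
are ellipses of diameter 14–24 px and aspect ≤ 1.5; floating cells are
discs of radius 4–8 px. Placement is rejection sampling with a default
surface-to-surface clearance of 16 px — a sparse field, as after serum
starvation — chosen so boundary lines of *distinct* cells can never
fall inside the 15 px duplicate-removal radius; overcrowding raises an
error rather than degrading silently. All randomness flows from the
mandatory seed through a single generator, so scenes are bit-for-bit
reproducible.

What the generator does **not** emulate: touching or overlapping cells,
curved (non-straight) slender cells, focus drift, vignetting beyond a
linear ramp, debris, and background texture. Passing recovery tests
therefore demonstrate that the pipeline implements its rules correctly
and is robust to the modeled noise — not that it reaches the same
accuracy on real confluent cultures, where overlap and curvature are
the dominant failure modes.

Recovery scoring matches detected polylines to true centerlines
greedily by midpoint distance, eligible within 15 px and 20° (the same
tolerances as the duplicate rule, since a detected line follows a
boundary offset up to half a cell width from the centerline). On small
instances the greedy assignment's total cost is within 10 % of the
enumerated optimum (tested).

## Numerical choices and degenerate inputs

* Zero-length segments are treated as points for distance, and are an
  error for angles (no direction).
* An empty edge image yields a valid all-zero accumulator and an empty
  result, not an error; a blank scene reports zero lines end to end.
* Strictness follows the stated wording everywhere: "fewer than 15 px",
  "less than 20°", so values exactly at a threshold do not trigger
  removal.
* Images smaller than 32×32 px are rejected; corrupt files in a batch
  are logged and skipped, and the batch fails only if no image loads.

## Problem sizes

Default test and acceptance scenes are 320×320 px with 10 cells, ten
seeds per condition — large enough that ten 70 px cells with 16 px
clearance place reliably, small enough that the whole suite runs in
seconds on one core. Accumulator-oracle checks run on ≤ 32×32 images
where exhaustive double-loop voting is cheap.

## Known limitations

* Reported length is boundary-line length, not cell length: on capsule
  ground truth the mean relative deviation is ~12 %, and the detector
  systematically reports the straight boundary side, which exceeds the
  centerline span near blurred cap ends.
* One line per slender cell presumes the duplicate rule removes the
  second boundary side — cells wider than 15 px would report two lines.
* Curved cells fragment into chained segments; merging recovers their
  total length only when gaps stay within `join_tol`.
* Confluent fields violate the clearance assumption; counts then drift
  low because neighboring parallel boundaries deduplicate each other.
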