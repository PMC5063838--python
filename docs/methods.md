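# Methods

## Problem and model

Leukocyte localization in stained smear images is cast as multi-circle
detection: a cell nucleus is approximated by a circle, and a circle is
fully determined by any three non-collinear points on its boundary. The
search space is therefore the set of index triples (e₁, e₂, e₃) into the
edge-pixel vector P extracted from the image, and the detector is a
stochastic combinatorial optimiser over that space rather than an
accumulator method (no Hough voting, no parameter grid).

### Pre-processing

1. RGB input is reduced to intensity with BT.601 luma weights
   (0.299, 0.587, 0.114).
2. An optional median filter (window 3 by default, `median_filter`)
   despeckles the intensity image before thresholding. This is the
   standard treatment for impulse noise in microscopy; without it,
   salt-and-pepper corruption floods the segmentation with single-pixel
   foreground and the edge map with speckle rings. Set to 0 to disable.
3. Histogram-threshold segmentation: Otsu's maximal between-class
   variance over the 256-bin histogram, unless an explicit threshold is
   given. Polarity is configurable (`foreground: dark|bright`), default
   dark, since leukocyte nuclei stain darker than the smear background.
   A constant image under auto-thresholding yields an all-background
   mask with a warning (fail-soft) or an error, per `on_constant`.
4. Edge map: by default Canny applied to the binary mask rendered 0/255
   (σ = 1; thresholds from the median rule low = 0.66·median,
   high = 1.33·median, falling back to the detector's quantile defaults
   when the median is degenerate). `edge_method: morph` instead takes
   the morphological boundary: foreground pixels removed by one erosion
   with a 3 × 3 cross — the smallest structuring element, giving a
   one-pixel ring. Both feed the identical EdgePixelVector contract
   (row-major order, 0-based x = column / y = row coordinates).

### Candidate geometry

The circumcircle of the three indexed edge points is computed from the
Cramer solution of the two perpendicular-bisector equations (2 × 2
determinants over the common denominator 4·((x_j−x_i)(y_k−y_i) −
(x_k−x_i)(y_j−y_i))); the radius is the centre-to-anchor distance, and
all three anchors agree to 1e-6 px by construction (property-tested
against an independent bisector-intersection solver). Collinear triples
(denominator below 1e-9 relative to the squared coordinate scale) are
degenerate and resampled. Candidates whose centre falls outside the
image or whose radius is outside [r_min, r_max] are rejected;
defaults r_min = 5 px (excludes speckle) and r_max = min(width,
height)/2 (excludes image-spanning arcs).

### Fitness

f(C) = 1 − coverage − W_p / max(B_p, 1), minimised.

* Coverage: the candidate's circumference is rasterised as every integer
  pixel within 0.5 px of the real-valued circle (a midpoint-style band;
  pixels outside the image are dropped), and coverage is the fraction of
  those pixels that are edge members. Membership uses a Chebyshev
  tolerance of 1 px by default (`edge_tolerance`). The tolerance matters:
  a one-pixel edge ring and the 0.5-px circumference band of the best
  inscribed circle are offset by up to about one pixel purely through
  rasterisation conventions, and exact membership (tolerance 0,
  available in config) deflates the coverage of geometrically perfect
  detections enough to drop below any reasonable acceptance threshold.
* Interior term: W_p and B_p count segmented-foreground and background
  pixels strictly inside the circle (distance < r; circumference pixels
  are not double-counted). The max(B_p, 1) guard keeps the value finite
  when the interior is pure foreground; in that regime the fitness is
  dominated by −W_p, so the optimiser maximises the enclosed white area
  — its minimum over a clean cell is the maximal inscribed circle of the
  cell body, which is the cell's own boundary circle. This also means
  fitness values on real scenes are large negative numbers; ranking, not
  magnitude, is what the search uses. The interior is counted on the
  segmented mask, not the edge map.

### The growth engine

The engine is objective-agnostic (it is exercised in the tests against a
pure integer toy objective). Root fitness f(R₀) = 1.0 — the supremum of
the fitness for any candidate with nonzero support — so every candidate
with any circumference or interior support is eligible. Concentrations
over live nodes: C_Ti = (f(R₀) − f(R_Ti)) / Σ_k (f(R₀) − f(R_Tk)); after
a node branches it retires with concentration exactly 0 and the same
formula reallocates over surviving trunk and branch nodes (the retired
node's deficit is dropped from both numerator and denominator).
Selection: the node whose cumulative-concentration interval contains a
uniform β (closed at 0 for the first node); deterministic given β.

Branch proposals (the neighbourhood search): with probability
p_explore = 0.1 a fresh uniform random triple; otherwise each index of
the selected node's triple is perturbed by a uniform offset in [−w, +w]
modulo N_p, with w = max(1, round(0.02·N_p)). Row-major edge ordering
makes index-adjacent pixels spatially coherent, so the perturbation is a
local move along image structures. Duplicate triples (order-free) are
collapsed; fitness ties break toward the earliest-created node, and the
engine owns a single seeded RNG stream, so runs are bit-reproducible.

Defaults: k = 30 initial particles, q = 10 proposals per branch,
patience = 10 improvement-free cycles, max_iterations = 200,
max_restarts = 5. These were chosen for the 360 × 363 scenes the package
targets (edge vectors of a few hundred to a few thousand pixels), where
a detection run takes well under a second.

### Multi-circle extraction and acceptance

After each engine run the best candidate is accepted iff its coverage is
at least α (default 0.5). Coverage, not raw fitness, is the acceptance
score because it is normalised to [0, 1] and directly measures how much
of the hypothesised boundary is actually present. On acceptance, all
edge pixels within δ = 2 px of the detected circumference are erased
from P (matching rasterisation width plus jitter) and the engine
restarts fresh on the remainder; the loop ends at the first
sub-threshold best, when fewer than 20 edge pixels remain, or at
max_circles = 20. Each acceptance strictly shrinks P (the anchor triple
is removed outright in the degenerate case), so termination is
guaranteed. Detecting partially hidden cells is a matter of lowering α
to the expected visible fraction — the occlusion experiment runs with
α = visible_fraction − 0.05.

## Synthetic scenes

The generator emulates the smear geometry the detector targets, not its
photometric texture: bright background (200), annular red-cell-like
distractors (150, pale centre), dark leukocyte discs (60; a 90 "bright
leukocyte" variant exists), on a 360 × 363 canvas. Cell radii default to
25–45 px; the clean profile places 3 non-overlapping cells plus 5
distractors per image. Five distractors (~4 % of pixels) keep the
trimodal histogram separable so Otsu isolates the leukocyte class — the
real pipeline likewise assumes segmentation isolates leukocytes from red
cells. Deformation is a 3-lobed sinusoidal radial perturbation
(amplitude = deformation·r, capped at 0.3); occlusion overpaints, with
background, a band of half-width 3 px along a contiguous boundary arc,
hiding that arc from the edge map while keeping the cell body (an
overlapped cell, not an absent one). Noise operators: additive Gaussian
(clipped, rounded) and salt-and-pepper hitting an exact pixel count
chosen without replacement, both seeded. Ground truth is exact by
construction and is never touched by corruption.

What the synthetic scenes do **not** model: staining texture and
gradients inside cells, cytoplasm halos, touching/overlapping cells,
uneven illumination, and colour. Passing the synthetic protocol
therefore demonstrates the geometry/search machinery and its noise
robustness, not photometric segmentation quality on real smears.

## Evaluation conventions

Matching is greedy one-to-one in ascending centre-distance order with
tolerances τ_c = 5 px and τ_r = 20 % relative radius — generous next to
the ≤ 2 px recovery property, strict enough to keep neighbouring cells
distinct. No true negative exists in a detection task, so the metric set
is precision (= PPV), sensitivity (= TPR), FDR, and an FPR whose
denominator is the expert-confirmed cell count; this FPR convention is
nonstandard and is flagged in the API (`fpr_definition`), with the
"standard" toggle reporting FPR as undefined rather than inventing a
negative class. Zero-denominator ratios are reported as null, never 0 or
100. PPV + FDR = 100 holds identically whenever any detection exists.

## Experiment sizes

The validation experiments run at desk scale: 1,000 allocation trials,
10,000 geometry triples and roulette draws, 20 single-circle scenes, 20
occlusion seeds, and 10 images per corruption level in the noise
benchmark — sizes at which every protocol completes in seconds to a few
minutes on one CPU while leaving the statistical assertions (binomial
standard errors, majority counts) meaningful.

## Known limitations

* Completely hidden cells are out of scope; the occlusion experiment
  requires the visible-arc fraction to be known to set α.
* The fitness's interior term assumes the segmentation isolates
  leukocytes; if red cells leak into the foreground class they become
  indistinguishable from cells to the detector.
* The W_p-dominated fitness landscape means the reported fitness value
  is scene-dependent and not comparable across images; use coverage for
  thresholds.
* The detector assumes roughly circular nuclei; strongly elliptical or
  lobed nuclei are localized by their inscribed circle at reduced
  coverage.
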