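# Methods

This note documents the models and procedures implemented in `dermoscan`,
their assumptions, the parameters that matter, and the design choices made
where the classical literature leaves details open.

## Synthetic dermoscopy model

Real dermoscopic images of pigmented lesions show a blob darker than the
surrounding skin with a gradually fading border, internal pigment texture,
and frequently occluding hairs.  The generator reproduces these properties
with a shape family chosen for exact ground truth: an ellipse (semi-axes
`a, b`, rotated) whose boundary radius is modulated as

```
m(θ) = 1 + w · sin(kθ)
```

with wobble amplitude `w ∈ [0, 1)` and `k` integer lobes.  A pixel belongs to
the lesion iff its normalised elliptical radius is ≤ `m(θ)`; the truth mask
is this crisp rasterization.  The rendered image blends lesion and skin
colours, blurs the transition with a Gaussian of σ = 2 px (`border_softness`,
emulating the fuzzy borders of real lesions), and adds i.i.d. Gaussian pixel
noise — `texture_noise_sd` inside the lesion, 4 gray levels on skin — clipped
to [0, 255].  Hairs are opaque dark quadratic Bézier strokes, 1–3 px wide.

Class conditions (drawn per sample; reference image size 256×256, geometry
scales with size):

| parameter | benign | malignant |
|---|---|---|
| major semi-axis a (px) | U(38, 52) | U(40, 54) |
| aspect b/a | U(0.85, 1.0) | U(0.55, 0.80) |
| wobble amplitude w | U(0.04, 0.12) | U(0.25, 0.35) |
| lobes k | 4–6 | 6–9 |
| lesion colour (RGB, ±10 jitter) | (125, 85, 60) | (70, 45, 35) |
| texture noise sd (gray levels) | U(4, 8) | U(16, 24) |
| hairs per image | 0–6 | 0–6 |

These gaps give the malignant class the clinical ABCD signature — higher
asymmetry, raggeder border, darker and more variegated colour, noisier
texture — strongly enough that a single roundness threshold separates ≥ 80%
of samples, which is the intended sanity floor for classifier tests.

**What the generator does not model:** pigment networks, globules and other
dermoscopic structures; vignetting and illumination gradients; ruler marks
and gel bubbles; multi-lesion fields; the three-way nevus/atypical/melanoma
distinction (labels are binary).  Passing tests therefore demonstrate that
the pipeline machinery is correct and self-consistent on images with these
statistics, not that its accuracy transfers to clinical data.

## Pre-processing

Stages run in the order: hair removal → grayscale → contrast stretch →
median → Gaussian → Lee → (optional) negative.  Each stage is individually
callable; the order is one defensible arrangement of the classical cleanup
chain, and the negative (max(I) − I) is off by default.

* **Hair removal** (DullRazor variant): each channel is median-smoothed
  (3×3) to suppress pixel noise, then grayscale-closed with flat line
  elements (length 9 px) at 0°/45°/90°/135°.  Pixels where the
  orientation-maximal closing exceeds the smoothed channel by > 25 gray
  levels are hair candidates; components smaller than 12 px are dropped, the
  mask is dilated 1 px, and flagged pixels take the closing's skin estimate.
  The threshold sits far below the hair/skin contrast (≳ 100 gray levels) and
  above noise-driven closing excursions.  Caveat: on strongly lobed borders
  the line closing also fills narrow boundary concavities (they are
  geometrically hair-like), touching ~2% of pixels there; on smooth-bordered
  lesions hair-free images pass through essentially unchanged.
* **Contrast stretch**: linear rescale between the clip/2 and 1−clip/2
  percentiles (default total clip 1%); constant images pass through, the
  mapping is monotone.
* **Lee filter**: `out = m + v/(v+σ_n²)·(I−m)` with local mean/variance over
  a 5×5 window and noise variance estimated as the mean local variance (the
  image provides no separate noise estimate).  Flat areas are smoothed to the
  mean, strong edges pass through.
* All windowed filters use replicate border padding; all stages preserve
  shape and the 8-bit range.

## Segmentation

**Adaptive snake.** An active contour initialised on a centered rectangle
(margin 0.12 of each dimension, chosen so the rectangle clears the largest
generated lesions) and contracted by a balloon force (−1), regularised by one
boundary-smoothing cycle per step, with the inverse-gradient stopping
function `g = 1/sqrt(1 + α|∇(G_σ*I)|)`, σ = 2, α = 300; the contour freezes
where `g < 0.35`.  Implemented as a morphological geodesic active contour
(scikit-image).  A parametric elasticity/rigidity snake was evaluated first
and abandoned: from a distant initialisation on textured images it stalls or
collapses for wide ranges of its weights, whereas the level-set form is
robust (mean pixel accuracy ≈ 0.996 on generator images, Dice 1.0 on a
noiseless disc).  Evolution runs in 20-iteration chunks up to 250 iterations;
convergence is declared when boundary displacement per iteration (changed
pixels / boundary length) drops below 0.1 px and is reported as metadata,
never as an exception.  `max_iterations = 0` returns the initial mask, and an
arbitrary `init_mask` may replace the rectangle (initialising on the true
boundary of a clean disc is a fixed point).

**Region growing.** Breadth-first growth from a seed (default: centroid of
the largest dark Otsu component of the smoothed image — lesions are dark),
accepting a neighbour when its intensity is within 30 gray levels of the
*running* region mean (updated incrementally; each pixel is examined once in
BFS order).  The raw region is then opened and closed with 2-px discs,
reduced to its largest component, and hole-filled.  8-connectivity by
default.  On soft borders the tolerance band stops growth where the blend
leaves ±τ of the lesion mean — systematically ~1–2 px inside the true
boundary — which is the mechanism behind the snake's consistent edge over RG
on these images (the snake settles on the gradient ridge, i.e. the true
border).

Both methods can run at a configurable working size (bilinear for images,
nearest-neighbour for masks on the way back); at the generator's native
256×256 no resizing occurs.

## Features

**GLCM.** Gray levels are quantized by linear binning of [0, 255] into 8
bins; co-occurrences are counted for pixel pairs *both inside the lesion
mask* (lesion texture is what discriminates), symmetrized (C + Cᵀ) and
normalized.  The 20 statistics use the standard Haralick/Soh/Clausi
definitions with 1-based indices and base-2 logarithms: autocorrelation,
contrast, correlation, cluster prominence, cluster shade, dissimilarity,
energy, entropy, homogeneity, maximum probability, sum of squares (variance,
centered on the GLCM mean), sum average, sum variance (centered on sum
average), sum entropy, difference variance, difference entropy, both
information measures of correlation, inverse difference normalized, and
inverse difference moment normalized.  Degenerate single-level matrices
yield correlation = IMC1 = 0 rather than NaN so feature vectors stay finite.
Statistics are averaged over offsets (1,0), (0,1), (1,1), (1,−1).

**Asymmetry.** The principal axes come from the mask's second moments; the
pixel set is reflected across each axis line, rounded to the grid, and
`ASI = 100·|S △ S'|/(2|S|)` is computed per axis; the headline value is the
mean of the major- and minor-axis values (both exposed).

**Perimeter.** The length of the marching-squares 0.5-level contour with a
3-point circular moving average of its vertices.  The smoothing cancels the
staircase bias of discrete boundaries: a radius-40 disc measures within ~1%
of 2π·40, a 2:1 ellipse within ~1% of Ramanujan's approximation, and the
window is small enough to preserve genuine boundary lobes.  Simple
(1, √2)-weighted chain-code counting was rejected because it overestimates
smooth boundaries by ~5–6%.  Border irregularity
`I = (ab/2π(a²+b²))·(P²/A)` (axis lengths from the second-moment ellipse) and
roundness `sqrt(4πA/P²)` both build on this estimator; for discrete squares
the pixel-center offset makes roundness approach its continuum value 0.886
only as the square grows.

**Colour.** Lesion pixels are converted to HSV; hue dispersion is the
circular variance (1 − resultant length), saturation variance is on the
[0, 1] scale, value variance in 8-bit units.  The scalar `color_variance`
feature is the sum of the three with value rescaled to [0, 1].

The feature vector has a fixed documented order (20 GLCM + asymmetry,
border irregularity, colour variance, area, diameter, roundness = 26
values); any non-finite entry raises an error naming the feature.  No
feature selection is applied.

## Classification

Features are standardized (fit on the training fold only, reapplied verbatim
at predict time).  The network has one hidden layer of 16 logistic units; the
default solver is full-batch L-BFGS, the reliable choice at the ~100-sample
scale this pipeline targets — with stochastic solvers (adam/sgd) training
uses a 10% validation hold-out and early stopping, but a 10-sample validation
set makes stopping noisy at this size.  The SVM uses an RBF kernel with C = 1
and scale-set gamma.  Splits are stratified 80/20, deterministic per seed;
every randomized step takes an explicit seed.  Non-convergence of the network
is recorded on the returned model as a warning, never raised.

## Evaluation

All seven metrics are computed from exact integer counts with floating
division last.  Zero denominators surface as explicit `undefined` markers in
the report, never as silent zeros.  Useful identities, verified by property
tests: Jaccard = F1/(2−F1) = TP/(TP+FP+FN); F1 is the harmonic mean of
precision and sensitivity; MCC is invariant under swapping the positive and
negative classes.

The reconstruction utility inverts printed percentage metrics: it searches
integer (TP, FP, FN, TN) with total ascending (ties: smallest TP) and accepts
a candidate when each computed percentage either rounds (half-up) or
truncates to the printed value at its printed precision — published tables
mix both conventions (e.g. 92.30 truncates 92.3077).  Published Jaccard
entries are consistent with F1/(2−F1) applied to the printed 2-decimal F1
rather than the unrounded value; the `verify-published-metrics` command prints this, and
also flags the one published entry (the network's MCC, 88.5) that no integer
matrix consistent with the row's other metrics can produce (the minimal
matrix gives 88.07).

## Problem sizes and determinism

The test suite and the acceptance script size their simulations for a single
CPU: the segmentation comparison uses 100 generated fixtures, the end-to-end
classification study 120 images (80 benign / 40 malignant, mirroring a 2:1
nevus/melanoma mix) at 256×256, the classifier-direction property 5 split
seeds.  A full acceptance run takes ~1.5 minutes; the complete test suite a
few minutes.  Every stochastic step (generation, splitting, network
initialisation) is seeded, and identical (input, config, seed) triples
reproduce identical outputs byte-for-byte.

## Known limitations

* Synthetic realism limits are listed above; none of the accuracy figures on
  generated data should be read as clinical performance.
* The snake assumes one dark lesion on lighter skin and returns a single
  connected region; multi-lesion images are out of scope.
* Region growing's tolerance is absolute (gray levels), so heavy global
  illumination changes would require re-tuning.
* The ABCDE "E" (evolution over time) has no meaning for single images and
  is not computed.
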