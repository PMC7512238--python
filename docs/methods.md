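# Methods

## The problem

Coherent-wave imaging modalities (ultrasound, SAR, some infrared sensors)
produce grayscale images contaminated by *speckle*: signal-dependent
multiplicative noise, `J = I + u·I`, whose local dispersion grows with the
local intensity. Histogram-based segmentation such as Otsu's method
degrades badly on such images because speckle smears the intensity modes
together. `ciseg` implements a statistical pre-filtering stage that
suppresses outlier pixels before thresholding, together with a from-scratch
multi-level Otsu segmenter, synthetic phantoms/noise models to evaluate the
chain end-to-end, and Jaccard/Dice/accuracy metrics.

## The confidence-interval pre-filter

All computation is on intensities in [0, 1] (integer images are divided by
their bit-depth maximum on load). The filter is a single pass:

1. Compute the population standard deviation σ of all pixel intensities
   (divide-by-N; the sample N−1 form is available via `sigma_ddof=1`).
2. Partition the image into `ia × ja` tiles, row-major; the last row and
   column of tiles absorb any remainder (ragged edges keep their true
   pixel count).
3. For each tile compute the sample mean x̄ of its pixels.
4. Keep a pixel `A` unchanged iff it lies *strictly* inside the
   normal-theory confidence band for the tile's population mean,

       x̄ − z·σ/√n  <  A  <  x̄ + z·σ/√n,

   otherwise replace it by the tile's representative statistic — x̄ by
   default, or the tile minimum/maximum under the alternative replacement
   policies.
5. Recompose the tiles into the output image.

σ and every x̄ come from the original image; replacements never feed back
into the statistics. The rationale: the band is where the tile's "high
content" mass concentrates, so intensities outside it are treated as noise
excursions and pulled back to the tile representative. The central limit
theorem justifies the normal quantile once the tile holds roughly n ≥ 30
pixels, regardless of the (non-Gaussian) speckle law.

Parameters, defaults and why:

* `z` — band half-width multiplier; defaults to the literal two-sided 95%
  value 1.96. If the user sets `confidence` instead, `z` is derived from
  the standard-normal quantile; `use_t=True` switches to a Student-t
  quantile with n−1 degrees of freedom (an off-by-default extension for
  small tiles, wider than the normal band).
* `tile` — defaults to 8×8 (n = 64), which satisfies the n ≥ 30 rule of
  thumb with a square footprint. A 4×13 tile (n = 52) is the closest
  rectangle to the historically used sample size of 52 pixels and is what
  the retention-fraction checks use; tile shape is always user-settable.
* `band_n` — sample size in the half-width for ragged edge tiles:
  `"nominal"` (default) always uses `ia·ja`, keeping the formula literal;
  `"actual"` uses the edge tile's true count.
* `replacement` — `mean` (default), `min` or `max`.

Consequences of the strict inequalities: on a constant image σ = 0, the
band is empty, every pixel is "replaced" by x̄ — which equals the constant,
so constant images are exact fixed points. On an i.i.d. Gaussian flat
field with n = 52 and z = 1.96 the expected kept fraction is
`2Φ(1.96/√52) − 1 ≈ 0.2142`: the band targets the *mean*, so on pure noise
it is deliberately aggressive, flattening most pixels toward the tile mean
while leaving genuine structure (which shifts tile means apart) intact.

## Multi-level Otsu

The segmenter operates on a 256-bin histogram by default (bin k covers
`[k/256, (k+1)/256)`, last bin closed; bin centers are the class
representatives). For m thresholds `t_1 < … < t_m` (bin indices) the
between-class variance is

    σ_B² = Σ_k ω_k (μ_k − μ_total)²

over the m+1 classes `t_k < b ≤ t_(k+1)` (sentinels t_0 = −1,
t_(m+1) = nbins−1); empty classes contribute zero. The search is globally
optimal over *all* strictly increasing m-tuples: cumulative zeroth/first
moments give each candidate class a score `s²/w` in O(1), and an exact
dynamic program over class boundaries (O(m·nbins²)) finds the maximizing
tuple. Ties are broken to the lexicographically smallest tuple, realized
by first-argmax backtracking — a fixed deterministic rule chosen for
reproducibility. The test-suite verifies the search against a literal
enumeration of every tuple on random histograms, and against
scikit-image's multi-Otsu as an independent cross-check; it also verifies
the decomposition σ_B² + σ_W² = σ_total² to 1e−10.

`m = 3` (four classes) is the default segmentation depth, matching common
practice for multi-level thresholding of piecewise scenes.

## Synthetic phantoms and noise

`make_phantom` builds piecewise-constant scenes: a background at the
lowest level plus one randomly placed, non-overlapping rectangle or disc
per remaining class, with class levels evenly spaced in [0.1, 0.9] and the
ground-truth label map returned alongside. Placement retries up to 200
times per shape and raises if the scene cannot be built. Shape footprints
are 12–35% of the image side, a range that keeps every class resolvable at
96×96 and above while leaving the background dominant, as in typical
single-object test scenes.

`add_speckle` draws a zero-mean uniform multiplier `u` on
`[−√(3v), +√(3v)]` (variance v), the convention of the classic `imnoise`
speckle generator; a Gaussian multiplier is an option. `add_gaussian` adds
i.i.d. `N(mean, variance)`. Both clip to [0, 1] after corruption;
moment-based tests use the pre-clip fields. All noise is driven by a
`numpy` `default_rng` seed and is bit-reproducible.

The default speckle multiplier variance is 0.30: measured over random
default phantoms it yields post-noise image standard deviations around
0.20 (median), inside the 0.15–0.27 band typical of visibly
speckle-contaminated natural test images. It was fixed once from that
dispersion requirement.

What the phantoms do *not* emulate: textured regions, smooth illumination
gradients, correlated (non-i.i.d.) speckle, and partial-volume boundary
mixing. Passing tests therefore demonstrate the statistical behaviour of
the filter and the optimality of the thresholding, not performance on any
particular clinical or remote-sensing dataset.

## Evaluation

`binarize` uses a strict `intensity > level` rule (level 0.5 by default;
a pixel exactly at the level is background — one convention fixed and
documented). `jaccard` returns J = |A∧B|/|A∨B| and Dice = 2J/(1+J); two
empty masks score 1 by convention. To score a colored/label segmentation
through the binary protocol, `render_labels` maps class k to its class
mean source intensity, mimicking a colored→gray→binary chain without
committing to a palette.

`label_accuracy` compares label maps after establishing class
correspondence: when source images are supplied, classes are renumbered by
ascending class mean intensity (the natural order for threshold-derived
labels); otherwise the agreement-maximizing one-to-one assignment on the
confusion matrix is used.

## Numerical choices and degenerate inputs

* Population (divide-by-N) σ by default; N−1 optional.
* Strict band inequalities exactly as stated; constant image ⇒ no-op.
* Histograms conserve pixel count; intensity 1.0 lands in the closed last
  bin.
* Threshold ties: lexicographically smallest tuple (e.g. a two-spike
  histogram with spikes at bins 64/192 returns threshold 64, the smallest
  of the tied range; a single-spike histogram returns 0).
* Empty Otsu classes contribute zero rather than raising.
* Image write quantization is round-half-up; a write/read round trip is
  exact to one quantization step.
* Coordinates are 0-based (row, col), tiles in row-major order.

## Known limitations

* On *clean* piecewise-constant images the pre-filter is not the identity:
  a tile straddling a region boundary has a mean between the levels and a
  band far narrower than the level gap, so the tile's minority pixels are
  flattened to the tile mean and subsequently labelled with the majority
  class. Measured on clean 256×256 4-class phantoms this costs ≈ 2–4% of
  pixels (all at region boundaries); the plain Otsu chain recovers such
  phantoms exactly. The filter's benefit appears once noise is present —
  under default speckle the pre-filtered pipeline's median accuracy is
  ≈ 0.95 vs ≈ 0.52 for plain Otsu at the same settings.
* The filter is single-pass by design; no iterative refinement.
* Color images are out of scope (inputs are collapsed to BT.601 luma).
* The exhaustive-optimal search is practical for m ≤ 4 at 256 bins; it is
  not a heuristic and does not scale to large m.

## Problem sizes used in the checks

The bundled verification runs use 8×8–32×32 images for the brute-force
filter oracle (100 images), histograms of ≤ 32 bins for the enumeration
oracle (200 histograms), a 520×520 flat field for the retention fraction,
and twenty 256×256 phantom seeds for the paired speckle comparison —
sizes at which every oracle is exact and the full run completes in
seconds.
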