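# ciseg

Segmentation of speckle-contaminated grayscale images with a
confidence-interval pre-filtering stage and multi-level Otsu thresholding.

Coherent-wave imaging (ultrasound, SAR, infrared) produces images degraded
by speckle — signal-dependent multiplicative noise `J = I + u·I` — which
smears the intensity histogram and breaks histogram-based segmenters such
as Otsu's method. `ciseg` is for engineers and researchers who want to run
and stress-test a statistical despeckling pre-stage ahead of multi-level
Otsu, end to end, on real images or on self-generated synthetic phantoms
with ground truth.

## The method

**Pre-filter.** With σ the population standard deviation of all pixel
intensities (each pixel a point-wise datum), the image is split into
`ia × ja` tiles. In each tile with sample mean x̄, a pixel `A` is kept iff
it lies strictly inside the normal-theory confidence band for the tile's
population mean μ,

    x̄ − z·σ/√n  <  A  <  x̄ + z·σ/√n,      n = ia·ja,  z = 1.96 (95%),

and is otherwise replaced by x̄ (tile min/max are alternative policies).
The tiles are recomposed into the pre-processed image. The central limit
theorem justifies the normal quantile for tiles of roughly n ≥ 30 pixels
whatever the speckle law; the band marks where the tile's information mass
sits, so excursions outside it are treated as noise and flattened.

**Segmentation.** A from-scratch m-level Otsu: on a 256-bin histogram the
search maximizes the between-class variance
`σ_B² = Σ_k ω_k (μ_k − μ_total)²` over *all* strictly increasing
threshold m-tuples (exact dynamic program, lexicographically smallest tie
winner), yielding m+1 classes. Default m = 3.

**Evaluation.** Jaccard `J = |A∩B|/|A∪B|` and Dice `2J/(1+J)` on
binarized images (strict `> 0.5` by default), plus per-pixel label
accuracy after class correspondence.

**Simulation.** Piecewise-constant phantoms (background + random
rectangles/discs, levels evenly spaced in [0.1, 0.9]) with ground-truth
labels; multiplicative speckle (zero-mean uniform multiplier) and additive
Gaussian noise, both seeded.

## Worked example

```sh
ciseg simulate phantom --size 256x256 --classes 4 --seed 1 \
      --out phantom.png --truth truth.png
ciseg simulate noise --kind speckle --variance 0.3 --seed 2 \
      --in phantom.png --out noisy.png
ciseg pipeline --in noisy.png --out labels.png --levels 3
ciseg segment  --in noisy.png --out labels_ref.png --levels 3 --no-prefilter
ciseg evaluate --pred labels.png     --truth truth.png
ciseg evaluate --pred labels_ref.png --truth truth.png
```

prints (stderr log interleaved with the scores):

```
ciseg: phantom: size=256x256 classes=4 seed=1 levels=[0.1, 0.3667, 0.6333, 0.9]
ciseg: noise: kind=speckle variance=0.3 mean=0 seed=2 post_sigma=0.146258
ciseg: pipeline: shape=(256, 256) sigma=0.146259 np=1024 retention=0.3435 thresholds=[29, 61, 124]
ciseg: segment: shape=(256, 256) m=3 thresholds=[27, 88, 189] classes=4
jaccard   0.297343
dice      0.458387
accuracy  0.837311      # CI pre-filter + Otsu
...
accuracy  0.523834      # plain Otsu on the same noisy image
```

Reading the log: the noisy image has σ ≈ 0.146; the filter's 1024 tiles
(8×8) kept 34% of pixels inside their bands and flattened the rest, after
which the three Otsu thresholds (bins 29/61/124) recover 83.7% of the
ground-truth pixels, against 52.4% for the reference chain without the
pre-stage. (The Jaccard/Dice rows binarize the class maps at mid-rank and
so only compare the dark/bright split; accuracy is the per-class score.)

The same chain is available in the library:

```python
import ciseg

ph = ciseg.make_phantom(256, 256, n_classes=4, seed=1)
noisy = ciseg.add_speckle(ph.image, ciseg.NoiseParams("speckle", 0.3, seed=2))
labels = ciseg.pipeline_segment(noisy, m=3)
print(ciseg.label_accuracy(labels, ph.labels))
```

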