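# Methods

## Density estimation and the ps-KDE transform

For a region r, the intensity density is a Gaussian kernel estimate over
the multiset of intensities at mask==1 pixels pooled across the training
images.  The estimate is tabulated on a uniform grid of G = 256 points on
[0, 1] inclusive (one point per 8-bit code value), truncated to the
intensity domain, and renormalized so the trapezoidal integral over the
grid is exactly 1 (enforced to 1e-9 and asserted by the model
invariants).  Off-grid queries are linearly interpolated between the two
bracketing grid points.

Fitting compresses the pixel multiset to unique values with exact
multiplicities before evaluating the kernel sum.  For 8-bit data this is
the 256-bin weighted histogram, and it is numerically identical to the
raw multiset fit for any input — the compression only reorders exact
additions — which keeps fitting O(unique · G) instead of O(pixels · G)
on multi-megapixel radiographs.

**Bandwidth.**  The kernel and bandwidth are free choices here; the
default is Scott's rule h = σ̂·n^(−1/5) on the pooled sample (the common
default of mainstream KDE routines), with an explicit numeric override.
A degenerate sample (n = 1 or σ̂ = 0) falls back to h = 1/255, one
quantization step, which keeps the model finite and peaked at the
observed value.

**Output normalization.**  The transform divides by the model's global
maximum density rather than per-image min–max.  Only a model-global
scaling makes the value→output mapping image-independent, which is what
"consistency among images" requires and what makes the
frequency-monotonicity property (higher density ⟺ higher output) hold
across images.  One model is fitted per structure and applied
independently, giving five enhanced variants per radiograph.

## Baselines

HE maps binned intensities through the normalized cumulative histogram
(256 bins by default); the mapping is monotone and idempotent up to one
bin width.  CLAHE partitions the image into a tile grid (default 8×8),
clips each tile's histogram at clip_limit × (tile pixels / n_bins)
(default clip_limit 2.0), redistributes the clipped excess in a single
deterministic pass — the integer share to every bin, the remainder one
count per bin from bin 0 upward — and blends the four surrounding tile
CDF mappings bilinearly, with clamped replication at borders.
Single-pass redistribution rather than iterative re-clipping is the
common reference behavior and is exactly mass-conserving, which the
implementation asserts per tile.  With one tile and an unbounded clip
limit CLAHE reduces to HE (verified within one bin width).

## Metrics, losses and statistics

Count-based metrics come from pixel confusion counts; probability maps
are thresholded at 0.5 before evaluation.  Conventions for degenerate
cases: any metric with an empty denominator (e.g. both masks empty)
returns 1, making all metrics total functions — the choice most
segmentation libraries make, and one that never triggers on the phantom
data since every region is non-empty.  BCE clips probabilities to
[1e-7, 1−1e-7]; the soft Jaccard and Dice losses add a 1e-7 smoothing
constant.  The combined loss is BCE + (1 − soft-IoU): adding a Jaccard
*loss* penalizes non-overlap, which is the only reading under which the
combined objective is coherent.  The Dice *loss* is the standard
1 − 2Σ(gt·pr)/(Σgt+Σpr).

Arms are compared per region with Welch's unequal-variance two-sample
t-test (Welch–Satterthwaite degrees of freedom, two-sided p from the t
distribution) on per-image Dice values, flagged at p < 0.01 with no
multiple-comparison correction.  Reports aggregate per-image values as
mean and sample SD (n−1 denominator; a single image reports SD 0 with
n = 1).

## Augmentation

Each augmented sample draws one composite transform — angle uniform on
[−90°, +90°], horizontal and vertical flips each Bernoulli(0.5), an
isotropic zoom factor uniform on [0.5, 1.5] — and applies it identically
to image and mask.  Flips are exact index reversals; rotation and zoom
share a single inverse affine resampling about the image center
(bilinear for the image, nearest-neighbor for the mask so binarity is
preserved); exposed borders fill with 0; both outputs are clamped to
[0, 1] and resized to 256×256 (bilinear/nearest).  Expanding a training
set applies k = 5 independently sampled transforms per original, so 124
originals yield exactly 620 training pairs.  The literal decomposition
into five isolated techniques is ambiguous in general; the composite
sampling is the deliberate design choice here since the downstream
pipeline only consumes the expanded set.

## The phantom generator

The generator emulates an annotated chest-radiograph dataset: a 256×256
image with two lung ellipses, a heart ellipse overlapping their medial
edges, and two tilted clavicle bars crossing the lung apices.  Pixel
ownership under overlap follows the projection priority clavicles >
heart > lungs > background, but the emitted masks are the full
rasterized shapes, mirroring independent per-structure annotations.
Intensities are normal per owning region — background 0.20 (SD 0.05),
lungs 0.35 (0.06), heart 0.65 (0.06), clavicles 0.80 (0.05) — plus a
global noise field (SD 0.02), clipped to [0, 1].  Clipping rather than
resampling keeps the generator deterministic and one-pass; the bias it
introduces is negligible at these means.  The separated means encode the
empirical premise of density-based enhancement — each structure owns a
distinct part of the histogram.  What the phantom does **not** emulate:
anatomical texture, rib shadows, scanner characteristics, or spatially
varying illumination.  Passing tests therefore demonstrate the
correctness and the mechanism of the methods, not clinical performance
on real radiographs.

## The evaluation pipeline

The experiment splits a dataset 50/50 by a seeded shuffle of file order,
fits any enhancement state (ps-KDE density models) on the training half
only, enhances both halves, trains the reference segmenter on the
training half, and evaluates on the validation half.  The reference
segmenter is a per-pixel Gaussian naive-Bayes classifier on intensity
(class-conditional normal fits with SDs floored at 1e-6, foreground
fraction as prior, posterior by Bayes' rule, threshold 0.5) — a
deliberately simple, deterministic, CPU-scale stand-in for a neural
segmenter that exercises the identical preprocessing, loss, metric and
probability-map machinery.  Because it classifies on intensity alone, it
is maximally sensitive to what the enhancement does to intensity
separability, which makes it a sharp instrument for comparing
preprocessing arms (and explains why CLAHE, which equalizes local
histograms and thus *removes* global intensity separability, scores
poorly under it).  Training-half augmentation is available
(`augment_k = 5` reproduces the 5× expansion) but defaults to off: a
pixel-pooling classifier is invariant to the geometric transforms, so
the default keeps the end-to-end run fast without changing its
conclusions.  Probability maps are written as plain 8-bit grayscale
PNGs.

## Problem sizes and numerical choices

The synthetic study in `scripts/acceptance.py` uses 20 phantoms at
256×256 (10 train / 10 validation) over all five regions and four arms,
which the package completes in seconds on one CPU.  Tolerances: density
unit mass 1e-9; oracle agreement for density fitting/interpolation 1e-9;
metric identities 1e-12; soft-vs-count metric agreement 1e-5 (set by the
smoothing constant); HE/CLAHE agreement one bin width.  Ties in the
naive-Bayes posterior (both likelihoods underflowing) resolve to 0.5.
Model JSON serialization uses Python's shortest round-trip float
representation, so save/load is bit-exact.

## Known limitations

* Densities are fitted at whatever resolution is supplied; intensity
  statistics drift slightly under resampling.
* The reference segmenter ignores all spatial context; its absolute Dice
  values are far below what a trained neural segmenter reaches and are
  meaningful only for comparing preprocessing arms under identical
  conditions.
* CLAHE parameters (clip limit 2.0, 8×8 tiles) are library-convention
  defaults; results depend on them.
* Only 8-bit grayscale PNG is supported — no DICOM, no color.
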