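# pskde

Organ-specific contrast enhancement for grayscale radiographs by
**pixel-wise substitution with kernel density estimates (ps-KDE)**,
together with the standard baselines (global histogram equalization and
CLAHE), pixel-level segmentation metrics and losses, paired image/mask
augmentation, a synthetic chest-phantom generator, and a command-line
pipeline that evaluates the enhancement methods end to end.

## The problem and the method

On a posterior-anterior chest radiograph, different anatomical structures
(heart, lungs, clavicles) occupy different parts of the pixel-intensity
histogram.  ps-KDE exploits that: for a chosen structure, the probability
density f̂(v) of pixel intensity v ∈ [0, 1] is estimated with a Gaussian
kernel from all pixels under that structure's masks in a training set,

    f̂(v) = (1 / n h) Σᵢ φ((v − xᵢ) / h),

truncated to [0, 1] and renormalized to unit trapezoidal mass on a
256-point grid.  Every pixel of an image is then replaced by the density
of its own intensity, scaled by the model's maximum:

    out(p) = f̂(image(p)) / max f̂.

Intensities that are common inside the target organ map near 1 and rare
ones map near 0, so the organ is lit up relative to its surround — and
because the value-to-output mapping depends only on the stored model, the
same intensity maps to the same output in every image, keeping images on
a consistent scale.  The bandwidth defaults to Scott's rule
h = σ̂·n^(−1/5); five independent models cover the five structures.

Around the core transform the package provides:

* `enhance` — HE and CLAHE (clip + single-pass redistribution + bilinear
  tile blending) as comparison preprocessors;
* `metrics` — IoU/Jaccard, Dice/F1 (= harmonic mean of precision and
  recall, = 2·IoU/(1+IoU)), precision, recall, accuracy, BCE, soft
  Jaccard/Dice losses, mean(SD) aggregation, and Welch's
  unequal-variance t-test;
* `augment` — paired geometric augmentation (rotation ±90°, flips at
  p = 0.5, zoom 0.5–1.5, resize to 256×256) with nearest-neighbor mask
  interpolation, expanding 124 training pairs into 620;
* `phantom` — a deterministic synthetic chest phantom (one image + five
  binary masks with distinct per-region intensity distributions) so the
  whole pipeline runs without any external dataset;
* `pipeline` / CLI — a seeded 50/50 split, per-arm enhancement, a
  Gaussian naive-Bayes pixel classifier as the desk-scale reference
  segmenter, Table-style mean(SD) reports and per-region Welch
  comparisons at p < 0.01.

## Worked example

```python
import numpy as np
from pskde import (PhantomConfig, generate_phantom, fit_density,
                   ps_kde_transform, contrast_gain)

cfg = PhantomConfig(seed=42)
rng = np.random.default_rng(42)
pairs = [generate_phantom(cfg, rng) for _ in range(10)]
model = fit_density([im for im, _ in pairs], [m["heart"] for _, m in pairs],
                    region_label="heart")
print(f"bandwidth h = {model.bandwidth:.4f}, n_pixels = {model.n_pixels}")
print(f"density peak at intensity {model.grid[np.argmax(model.density)]:.3f}")

img, masks = pairs[0]
enhanced = ps_kde_transform(img, model)
raw, enh = contrast_gain(img, enhanced, masks["heart"])
print(f"heart/surround separation: raw {raw:.2f} -> ps-KDE {enh:.2f}")
```

prints

```
bandwidth h = 0.0074, n_pixels = 44770
density peak at intensity 0.651
heart/surround separation: raw 3.17 -> ps-KDE 8.46
```

The fitted heart density peaks at 0.651, recovering the phantom's
configured heart intensity mean of 0.65; substituting densities raises
the heart's separation from its surround (|Δmean| / pooled SD) from 3.17
to 8.46 on the first phantom.

The same workflow from the shell:

```
pskde phantom --n 20 --seed 42 --out data/
pskde fit-kde --images data/images --masks data/masks --region heart --out heart.json
pskde enhance --method pskde --in data/images --out enhanced/ --model heart.json
pskde run --data data/ --methods none,pskde --seed 42 --out results/
pskde compare --a results/per_image_none.csv --b results/per_image_pskde.csv --out cmp.csv
```

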