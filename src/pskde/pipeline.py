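"""End-to-end experiment orchestration at desk scale.

The pipeline mirrors the evaluation protocol around the enhancement
methods: split a dataset 50/50 into training and validation halves by a
seeded shuffle, optionally expand the training half five-fold by paired
augmentation, fit the enhancement (ps-KDE density models come from the
training half only), enhance both halves, train a per-region reference
segmenter on the training half, predict foreground probability on the
validation half, threshold at 0.5, and report the five metrics as
mean(SD) plus per-image values.  Two arms are compared per region with
the unequal-variance t-test on their per-image Dice scores at the p<0.01
significance level, without multiplicity correction.

The reference segmenter is a per-pixel Gaussian naive-Bayes classifier on
intensity: class-conditional normal fits for foreground and background
with the foreground pixel fraction as prior.  It is a deliberately simple,
deterministic, CPU-scale segmenter whose probability output feeds exactly
the same loss/metric/heatmap machinery a neural segmenter would.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .augment import AugmentConfig, expand_dataset
from .enhance import ClaheConfig, clahe, hist_equalize
from .images import REGIONS, load_image, load_mask, save_image, validate_image
from .kde import DensityModel, fit_density, ps_kde_transform
from .metrics import aggregate_report, all_metrics, confusion, welch_t_test

logger = logging.getLogger("pskde")

METHODS = ("none", "he", "clahe", "pskde")

#: Probability threshold turning a probability map into a predicted mask.
PRED_THRESHOLD = 0.5

#: Significance level for method comparisons (uncorrected).
ALPHA = 0.01


@dataclass(frozen=True)
class PixelClassifier:
    """Gaussian naive-Bayes pixel classifier on intensity.

    Class-conditional N(mean, sd) for foreground and background, sds
    floored at 1e-6, with the foreground pixel fraction as prior.
    """

    fg_mean: float
    fg_sd: float
    bg_mean: float
    bg_sd: float
    prior: float

    def __post_init__(self) -> None:
        if not (self.fg_sd > 0.0 and self.bg_sd > 0.0):
            raise ValueError("classifier sds must be positive")
        if not (0.0 < self.prior < 1.0):
            raise ValueError("prior must lie in (0, 1)")


def train_pixel_classifier(
    images: Sequence[np.ndarray], masks: Sequence[np.ndarray]
) -> PixelClassifier:
    """Fit class-conditional Gaussians on pixel intensity; deterministic."""
    if len(images) == 0 or len(images) != len(masks):
        raise ValueError("images and masks must be non-empty lists of equal length")
    fg_vals = []
    bg_vals = []
    for img, msk in zip(images, masks):
        img = np.asarray(img, dtype=np.float64)
        msk = np.asarray(msk)
        fg_vals.append(img[msk == 1])
        bg_vals.append(img[msk == 0])
    fg = np.concatenate(fg_vals)
    bg = np.concatenate(bg_vals)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("degenerate training labels")
    floor = 1e-6
    return PixelClassifier(
        fg_mean=float(fg.mean()),
        fg_sd=max(float(fg.std()), floor),
        bg_mean=float(bg.mean()),
        bg_sd=max(float(bg.std()), floor),
        prior=fg.size / (fg.size + bg.size),
    )


def predict_probability(image: np.ndarray, clf: PixelClassifier) -> np.ndarray:
    """Per-pixel posterior foreground probability via Bayes' rule."""
    img = validate_image(image)
    lf = stats.norm.pdf(img, clf.fg_mean, clf.fg_sd) * clf.prior
    lb = stats.norm.pdf(img, clf.bg_mean, clf.bg_sd) * (1.0 - clf.prior)
    denom = lf + lb
    # Both likelihoods can underflow far in the tails; split the tie evenly.
    post = np.where(denom > 0.0, lf / np.where(denom > 0.0, denom, 1.0), 0.5)
    return np.clip(post, 0.0, 1.0)


def enhance_image(
    image: np.ndarray,
    method: str,
    model: DensityModel | None = None,
    clahe_config: ClaheConfig | None = None,
) -> np.ndarray:
    """Apply one enhancement arm: none, he, clahe, or pskde."""
    if method == "none":
        return validate_image(image)
    if method == "he":
        return hist_equalize(image)
    if method == "clahe":
        return clahe(image, clahe_config)
    if method == "pskde":
        if model is None:
            raise ValueError("pskde enhancement requires a density model")
        return ps_kde_transform(image, model)
    raise ValueError(f"unknown method name: {method}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Configuration for :func:`run_experiment`."""

    data_dir: str
    out_dir: str
    regions: tuple[str, ...] = REGIONS
    methods: tuple[str, ...] = ("none", "pskde")
    seed: int = 0
    split: float = 0.5
    augment_k: int = 0  # 0 disables training-set augmentation; 5 matches the recipe
    clahe_config: ClaheConfig = field(default_factory=ClaheConfig)
    write_probmaps: bool = True


def _load_dataset(
    data_dir: Path, regions: Sequence[str]
) -> tuple[list[str], list[np.ndarray], dict[str, list[np.ndarray]]]:
    image_paths = sorted((data_dir / "images").glob("*.png"))
    if not image_paths:
        raise ValueError(f"no images found under {data_dir}/images")
    names = [p.stem for p in image_paths]
    images = [load_image(p) for p in image_paths]
    masks = {
        region: [load_mask(data_dir / "masks" / region / f"{n}.png") for n in names]
        for region in regions
    }
    return names, images, masks


def _split_indices(n: int, split: float, seed: int) -> tuple[list[int], list[int]]:
    """Seeded shuffle of file order, then a train/validation cut."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(n * split))
    n_train = min(max(n_train, 1), n - 1)
    return sorted(order[:n_train].tolist()), sorted(order[n_train:].tolist())


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run every (region, method) arm and write Table-style reports.

    Writes, under ``config.out_dir``: ``report_<method>.csv`` (mean/SD per
    region and metric), ``per_image_<method>.csv`` (per-image metric
    values), ``split.csv`` (which files trained and which validated), and
    8-bit grayscale probability-map PNGs under ``probmaps/``.  Fully
    deterministic under a fixed seed; density models and classifiers see
    the training half only.
    """
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for method in config.methods:
        if method not in METHODS:
            raise ValueError(f"unknown method name: {method}")

    names, images, masks = _load_dataset(data_dir, config.regions)
    train_idx, val_idx = _split_indices(len(names), config.split, config.seed)
    logger.info("dataset %s: %d train / %d validation", data_dir, len(train_idx), len(val_idx))

    pd.DataFrame(
        {
            "name": [names[i] for i in train_idx + val_idx],
            "split": ["train"] * len(train_idx) + ["validation"] * len(val_idx),
        }
    ).to_csv(out_dir / "split.csv", index=False)

    reports = []
    per_image_frames = []
    for method in config.methods:
        for region in config.regions:
            train_imgs = [images[i] for i in train_idx]
            train_masks = [masks[region][i] for i in train_idx]
            val_imgs = [images[i] for i in val_idx]
            val_masks = [masks[region][i] for i in val_idx]
            val_names = [names[i] for i in val_idx]

            if config.augment_k > 0:
                aug_cfg = AugmentConfig(seed=config.seed)
                pairs = expand_dataset(train_imgs, train_masks, aug_cfg, k=config.augment_k)
                train_imgs = [p[0] for p in pairs]
                train_masks = [p[1] for p in pairs]

            model = None
            if method == "pskde":
                model = fit_density(train_imgs, train_masks, region_label=region)

            enh_train = [
                enhance_image(im, method, model, config.clahe_config) for im in train_imgs
            ]
            enh_val = [
                enhance_image(im, method, model, config.clahe_config) for im in val_imgs
            ]

            clf = train_pixel_classifier(enh_train, train_masks)
            logger.info("arm method=%s region=%s classifier=%s", method, region, clf)

            rows = []
            per_image = []
            for name, img, gt in zip(val_names, enh_val, val_masks):
                prob = predict_probability(img, clf)
                pred = (prob >= PRED_THRESHOLD).astype(np.uint8)
                m = all_metrics(confusion(gt, pred))
                per_image.append(m)
                rows.append({"name": name, "region": region, "method": method, **m})
                if config.write_probmaps:
                    pm_dir = out_dir / "probmaps" / method / region
                    pm_dir.mkdir(parents=True, exist_ok=True)
                    save_image(prob, pm_dir / f"{name}.png")

            reports.append(aggregate_report(per_image, region, method))
            per_image_frames.append(pd.DataFrame(rows))

    report = pd.concat(reports, ignore_index=True).sort_values(
        ["region", "method", "metric"], ignore_index=True
    )
    per_image_all = pd.concat(per_image_frames, ignore_index=True)
    for method in config.methods:
        report[report["method"] == method].to_csv(
            out_dir / f"report_{method}.csv", index=False
        )
        per_image_all[per_image_all["method"] == method].to_csv(
            out_dir / f"per_image_{method}.csv", index=False
        )
    return report


def compare_methods(
    per_image_a: pd.DataFrame, per_image_b: pd.DataFrame, metric: str = "Dice"
) -> pd.DataFrame:
    """Welch-compare two arms' per-image scores region by region.

    Expects per-image frames as written by :func:`run_experiment` (columns
    name, region, method, Accuracy, Dice, IoU, Precision, Recall).  Flags
    significance at p < 0.01 with no multiple-comparison correction.
    """
    rows = []
    regions = sorted(set(per_image_a["region"]) & set(per_image_b["region"]))
    if not regions:
        raise ValueError("no shared regions to compare")
    method_a = per_image_a["method"].iloc[0]
    method_b = per_image_b["method"].iloc[0]
    for region in regions:
        a = per_image_a.loc[per_image_a["region"] == region, metric].to_numpy()
        b = per_image_b.loc[per_image_b["region"] == region, metric].to_numpy()
        if np.array_equal(a, b):
            t, df, p = 0.0, float(len(a) + len(b) - 2), 1.0
        else:
            t, df, p = welch_t_test(a, b)
        rows.append(
            {
                "region": region,
                "method_a": method_a,
                "method_b": method_b,
                "metric": metric,
                "t": t,
                "df": df,
                "p": p,
                "significant": p < ALPHA,
            }
        )
    return pd.DataFrame(rows)


def contrast_gain(
    image: np.ndarray, enhanced: np.ndarray, mask: np.ndarray
) -> tuple[float, float]:
    """Separation of a region from its surround, before and after enhancement.

    Returns ``(raw, enhanced)`` where each is |mean inside - mean outside|
    divided by the pooled standard deviation of the two groups.
    """

    def _gain(arr: np.ndarray) -> float:
        inside = arr[mask == 1]
        outside = arr[mask == 0]
        pooled = np.sqrt(
            (
                (inside.size - 1) * inside.var(ddof=1)
                + (outside.size - 1) * outside.var(ddof=1)
            )
            / (inside.size + outside.size - 2)
        )
        return float(abs(inside.mean() - outside.mean()) / pooled)

    return _gain(np.asarray(image, float)), _gain(np.asarray(enhanced, float))


def hash_file(path: str | Path) -> str:
    """SHA-256 of a file, for byte-reproducibility checks."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
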