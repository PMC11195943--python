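"""Pixel-wise substitution by kernel density estimation (ps-KDE).

The enhancement works in two stages.  First, for one anatomical region, the
probability density of pixel intensity is estimated from all pixels under
that region's masks in a training set, using a Gaussian kernel on a fixed
uniform grid over ``[0, 1]`` and truncation-renormalization so the density
integrates to exactly one on the intensity domain.  The fitted density is
the region's *prior knowledge* and can be stored to JSON.  Second, every
pixel of an image is replaced by the estimated density of its intensity,
and the result is divided by the model's maximum grid density so the output
lies in ``[0, 1]``.  Because the value-to-output mapping depends only on
the model, the same intensity maps to the same output in every image
enhanced with that model, and more frequent intensities map to higher
outputs.

Bandwidth defaults to Scott's rule ``h = sigma * n**(-1/5)`` on the pooled
masked-pixel sample, falling back to one 8-bit quantization step (1/255)
when the sample is degenerate (a single pixel or zero spread).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .images import check_pair, validate_image, validate_mask

#: Fallback bandwidth for degenerate samples: one 8-bit quantization step.
EPS_BANDWIDTH = 1.0 / 255.0

#: Default number of uniform grid points on [0, 1], matching 8-bit depth.
DEFAULT_GRID_SIZE = 256

_SCHEMA_VERSION = 1


@dataclass
class DensityModel:
    """A per-region intensity density on a uniform grid over [0, 1].

    Attributes
    ----------
    region_label : str
        Which anatomical structure the model was fitted for.
    grid : ndarray
        ``G`` uniformly spaced intensity points spanning [0, 1] inclusive.
    density : ndarray
        ``G`` non-negative values; trapezoidal integral over ``grid`` is 1.
    bandwidth : float
        Gaussian kernel bandwidth ``h`` in intensity units, > 0.
    n_pixels : int
        Number of training pixels pooled into the fit.
    """

    region_label: str
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_pixels: int
    max_density: float = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.density = np.asarray(self.density, dtype=np.float64)
        self.validate()
        self.max_density = float(self.density.max())

    def validate(self) -> None:
        g, d = self.grid, self.density
        if g.ndim != 1 or g.size < 2 or d.shape != g.shape:
            raise ValueError("invalid density model file")
        expected = np.linspace(0.0, 1.0, g.size)
        if not np.allclose(g, expected, atol=1e-12, rtol=0.0):
            raise ValueError("invalid density model file")
        if not np.all(np.isfinite(d)) or d.min() < 0.0 or d.max() <= 0.0:
            raise ValueError("invalid density model file")
        if abs(np.trapezoid(d, g) - 1.0) > 1e-9:
            raise ValueError("invalid density model file")
        if not (self.bandwidth > 0.0):
            raise ValueError("invalid bandwidth")
        if int(self.n_pixels) < 1:
            raise ValueError("invalid density model file")


def scott_bandwidth(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Scott's rule ``h = sigma * n**(-1/5)`` with a quantization-step floor.

    ``sigma`` is the sample standard deviation (n-1 denominator).  A sample
    of one pixel, or one with zero spread, returns the fallback 1/255.
    """
    values = np.asarray(values, dtype=np.float64)
    if weights is None:
        weights = np.ones_like(values)
    n = float(weights.sum())
    if n < 2:
        return EPS_BANDWIDTH
    mean = float(np.sum(weights * values) / n)
    var = float(np.sum(weights * (values - mean) ** 2) / (n - 1.0))
    sigma = math.sqrt(var)
    if sigma <= 0.0:
        return EPS_BANDWIDTH
    return sigma * n ** (-0.2)


def fit_density(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    *,
    region_label: str = "region",
    bandwidth: str | float = "scott",
    grid_size: int = DEFAULT_GRID_SIZE,
) -> DensityModel:
    """Fit a region's intensity density from paired training images/masks.

    Pools the intensities at mask==1 pixels over the collection, compresses
    the pooled multiset to unique values with counts (exact, and O(256)
    for 8-bit-quantized data), evaluates the Gaussian kernel sum on the
    grid and renormalizes the truncated density to unit trapezoidal
    integral over [0, 1].  Deterministic: no randomness anywhere.

    Parameters
    ----------
    bandwidth : "scott" or positive float
        Kernel bandwidth rule or explicit value in intensity units.
    grid_size : int
        Number of uniform grid points on [0, 1] inclusive (>= 2).
    """
    if len(images) == 0 or len(images) != len(masks):
        raise ValueError("images and masks must be non-empty lists of equal length")
    if grid_size < 2:
        raise ValueError("grid_size must be at least 2")

    pooled = []
    for img, msk in zip(images, masks):
        img = validate_image(img)
        msk = validate_mask(msk)
        check_pair(img, msk)
        pooled.append(img[msk == 1])
    values = np.concatenate(pooled)
    if values.size == 0:
        raise ValueError("no training pixels for region")

    # Weighted-histogram compression: identical to the raw multiset because
    # unique values carry their exact multiplicities.
    uniq, counts = np.unique(values, return_counts=True)
    weights = counts.astype(np.float64)
    n = float(weights.sum())

    if isinstance(bandwidth, str):
        if bandwidth != "scott":
            raise ValueError("invalid bandwidth")
        h = scott_bandwidth(uniq, weights)
    else:
        h = float(bandwidth)
        if not (h > 0.0) or not math.isfinite(h):
            raise ValueError("invalid bandwidth")

    grid = np.linspace(0.0, 1.0, grid_size)
    # Gaussian kernel sum: (1/(n h)) sum_i w_i phi((g - x_i)/h)
    z = (grid[:, None] - uniq[None, :]) / h
    kern = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    density = kern @ weights / (n * h)
    mass = np.trapezoid(density, grid)
    if mass <= 0.0:
        raise ValueError("no training pixels for region")
    density = density / mass

    return DensityModel(
        region_label=region_label,
        grid=grid,
        density=density,
        bandwidth=h,
        n_pixels=int(round(n)),
    )


def density_at(model: DensityModel, v: float | np.ndarray) -> float | np.ndarray:
    """Evaluate the model density at intensity ``v`` by linear interpolation.

    Exact tabulated value when ``v`` hits a grid point; raises for
    intensities outside [0, 1].
    """
    arr = np.asarray(v, dtype=np.float64)
    if not np.all(np.isfinite(arr)) or arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("intensity out of range")
    out = np.interp(arr, model.grid, model.density)
    if np.isscalar(v) or arr.ndim == 0:
        return float(out)
    return out


def ps_kde_transform(image: np.ndarray, model: DensityModel) -> np.ndarray:
    """Substitute each pixel with its density, scaled by the model maximum.

    ``out(p) = density_at(model, image(p)) / model.max_density`` — the
    mapping depends only on the model, so images sharing a model are on a
    common scale and equal input intensities always give equal outputs.
    """
    img = validate_image(image)
    return density_at(model, img) / model.max_density


def save_model(model: DensityModel, path: str | os.PathLike) -> None:
    """Serialize a model to JSON (floats round-trip bit-exactly)."""
    payload = {
        "schema_version": _SCHEMA_VERSION,
        "region_label": model.region_label,
        "grid": [float(x) for x in model.grid],
        "density": [float(x) for x in model.density],
        "bandwidth": float(model.bandwidth),
        "n_pixels": int(model.n_pixels),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | os.PathLike) -> DensityModel:
    """Load a model saved by :func:`save_model`; max_density is recomputed."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError("invalid density model file") from exc
    if not isinstance(payload, dict):
        raise ValueError("invalid density model file")
    version = payload.get("schema_version")
    if version != _SCHEMA_VERSION:
        raise ValueError("unsupported model version")
    required = {"region_label", "grid", "density", "bandwidth", "n_pixels"}
    if not required.issubset(payload):
        raise ValueError("invalid density model file")
    try:
        return DensityModel(
            region_label=str(payload["region_label"]),
            grid=np.asarray(payload["grid"], dtype=np.float64),
            density=np.asarray(payload["density"], dtype=np.float64),
            bandwidth=float(payload["bandwidth"]),
            n_pixels=int(payload["n_pixels"]),
        )
    except (TypeError, KeyError) as exc:
        raise ValueError("invalid density model file") from exc
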