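"""Grayscale image and binary region-mask containers and PNG I/O.

The in-memory convention used throughout the package:

* a *gray image* is a 2-D ``float64`` array with every value in ``[0, 1]``;
* a *region mask* is a 2-D ``uint8`` array with values in ``{0, 1}``.

On disk both are 8-bit grayscale PNG.  Images map ``{0..255}`` to
``value / 255`` exactly on load and round ``value * 255`` to the nearest
integer on save.  Masks are stored as ``{0, 255}``; any nonzero on-disk
value reads back as 1.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
from PIL import Image

#: The five anatomical structures annotated per chest radiograph.
REGIONS = ("heart", "left_lung", "right_lung", "left_clavicle", "right_clavicle")


def validate_image(pixels: np.ndarray) -> np.ndarray:
    """Check a gray-image array and return it as float64.

    Raises
    ------
    ValueError
        If the array is not 2-D, contains non-finite values, or has
        values outside ``[0, 1]``.
    """
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must be a 2-D array with positive dimensions")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image values outside [0, 1]")
    return arr


def validate_mask(pixels: np.ndarray) -> np.ndarray:
    """Check a region-mask array and return it as uint8 in {0, 1}."""
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("mask must be a 2-D array with positive dimensions")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask values must be strictly binary")
    return arr.astype(np.uint8)


def check_pair(image: np.ndarray, mask: np.ndarray) -> None:
    """Raise if an image and its mask do not share a shape."""
    if image.shape != mask.shape:
        raise ValueError("image/mask shape mismatch")


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Load an 8-bit grayscale PNG as a float image in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def save_image(image: np.ndarray, path: str | os.PathLike) -> None:
    """Save a float image in [0, 1] as an 8-bit grayscale PNG."""
    arr = validate_image(image)
    quant = np.rint(arr * 255.0).astype(np.uint8)
    Image.fromarray(quant, mode="L").save(path, format="PNG")


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Load a binary mask PNG; any nonzero pixel reads as 1."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr != 0).astype(np.uint8)


def save_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Save a {0, 1} mask as a {0, 255} 8-bit grayscale PNG."""
    arr = validate_mask(mask)
    Image.fromarray(arr * np.uint8(255), mode="L").save(path, format="PNG")


def quantize8(image: np.ndarray) -> np.ndarray:
    """Round a float image to the 8-bit grid (values k/255)."""
    return np.rint(np.asarray(image, dtype=np.float64) * 255.0) / 255.0


def masked_values(
    images: Iterable[np.ndarray], masks: Iterable[np.ndarray]
) -> np.ndarray:
    """Pool the intensities at mask==1 pixels over paired image/mask lists."""
    pooled = []
    for img, msk in zip(images, masks, strict=True):
        img = validate_image(img)
        msk = validate_mask(msk)
        check_pair(img, msk)
        pooled.append(img[msk == 1])
    if not pooled:
        return np.empty(0, dtype=np.float64)
    return np.concatenate(pooled)
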