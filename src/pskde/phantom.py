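"""Synthetic chest-phantom generator.

Emulates the structure of an annotated chest-radiograph dataset — one
grayscale image plus five binary masks (heart, left lung, right lung, left
clavicle, right clavicle) per case — with a controllable, clearly distinct
pixel-intensity distribution per region.  That distinctness is the working
premise of density-based enhancement: each structure occupies its own part
of the intensity histogram, so a region-specific density model can light
it up.

Geometry is deliberately simple: two lung ellipses, a heart ellipse
overlapping their medial edges, and two thin tilted clavicle bars crossing
the lung apices.  Where shapes overlap, pixel ownership follows the
projection-radiograph priority clavicles > heart > lungs > background, but
each emitted mask is the full rasterized shape, mirroring independent
per-structure annotations.  Intensities are drawn per pixel from the
owning region's normal distribution, a global noise field is added, and
the result is clipped to [0, 1].
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .images import REGIONS, save_image, save_mask


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (row, col) and semi-axes (a_row, a_col)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]


@dataclass(frozen=True)
class Bar:
    """Tilted bar: center (row, col), half-length, half-thickness, angle (deg)."""

    center: tuple[float, float]
    half_length: float
    half_thickness: float
    angle: float


def _default_geometry() -> dict[str, object]:
    # Laid out for a 256x256 frame; scaled proportionally for other sizes.
    return {
        "heart": Ellipse(center=(152.0, 128.0), semi_axes=(42.0, 34.0)),
        "left_lung": Ellipse(center=(118.0, 178.0), semi_axes=(72.0, 40.0)),
        "right_lung": Ellipse(center=(118.0, 78.0), semi_axes=(72.0, 40.0)),
        "left_clavicle": Bar(
            center=(52.0, 178.0), half_length=44.0, half_thickness=5.0, angle=-12.0
        ),
        "right_clavicle": Bar(
            center=(52.0, 78.0), half_length=44.0, half_thickness=5.0, angle=12.0
        ),
    }


def _default_intensity() -> dict[str, tuple[float, float]]:
    return {
        "background": (0.20, 0.05),
        "left_lung": (0.35, 0.06),
        "right_lung": (0.35, 0.06),
        "heart": (0.65, 0.06),
        "left_clavicle": (0.80, 0.05),
        "right_clavicle": (0.80, 0.05),
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry, per-region intensity statistics, noise and seed.

    ``intensity`` maps region name (plus "background") to (mean, sd) in
    [0, 1] intensity units; ``noise_sd`` is the global additive noise.
    """

    size: tuple[int, int] = (256, 256)
    geometry: dict[str, object] = field(default_factory=_default_geometry)
    intensity: dict[str, tuple[float, float]] = field(default_factory=_default_intensity)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size[0] < 1 or self.size[1] < 1:
            raise ValueError("size must be positive")
        for name, (mean, sd) in self.intensity.items():
            if not (0.0 <= mean <= 1.0):
                raise ValueError(f"intensity mean for {name} outside [0, 1]")
            if sd < 0.0:
                raise ValueError(f"intensity sd for {name} negative")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be non-negative")


def _scale_geometry(config: PhantomConfig) -> dict[str, object]:
    """Scale the 256-frame geometry to the configured image size."""
    sy = config.size[0] / 256.0
    sx = config.size[1] / 256.0
    scaled: dict[str, object] = {}
    for name, shape in config.geometry.items():
        if isinstance(shape, Ellipse):
            scaled[name] = Ellipse(
                center=(shape.center[0] * sy, shape.center[1] * sx),
                semi_axes=(shape.semi_axes[0] * sy, shape.semi_axes[1] * sx),
            )
        elif isinstance(shape, Bar):
            s = min(sy, sx)
            scaled[name] = Bar(
                center=(shape.center[0] * sy, shape.center[1] * sx),
                half_length=shape.half_length * s,
                half_thickness=shape.half_thickness * s,
                angle=shape.angle,
            )
        else:  # pragma: no cover - config contract
            raise TypeError(f"unknown shape for region {name}")
    return scaled


def _rasterize(shape: object, size: tuple[int, int]) -> np.ndarray:
    rows, cols = np.mgrid[0 : size[0], 0 : size[1]].astype(np.float64)
    if isinstance(shape, Ellipse):
        (cy, cx), (ay, ax) = shape.center, shape.semi_axes
        return ((rows - cy) / ay) ** 2 + ((cols - cx) / ax) ** 2 <= 1.0
    if isinstance(shape, Bar):
        theta = np.deg2rad(shape.angle)
        dy = rows - shape.center[0]
        dx = cols - shape.center[1]
        # coordinates along/across the bar axis
        along = dx * np.cos(theta) + dy * np.sin(theta)
        across = -dx * np.sin(theta) + dy * np.cos(theta)
        return (np.abs(along) <= shape.half_length) & (
            np.abs(across) <= shape.half_thickness
        )
    raise TypeError("unknown shape")


def _check_bounds(shape: object, size: tuple[int, int]) -> None:
    if isinstance(shape, Ellipse):
        (cy, cx), (ay, ax) = shape.center, shape.semi_axes
        lo = (cy - ay, cx - ax)
        hi = (cy + ay, cx + ax)
    elif isinstance(shape, Bar):
        r = np.hypot(shape.half_length, shape.half_thickness)
        lo = (shape.center[0] - r, shape.center[1] - r)
        hi = (shape.center[0] + r, shape.center[1] + r)
    else:
        raise TypeError("unknown shape")
    if lo[0] < 0 or lo[1] < 0 or hi[0] > size[0] - 1 or hi[1] > size[1] - 1:
        raise ValueError("geometry out of bounds")


#: Pixel-ownership priority on a projection radiograph (first wins).
_PRIORITY = ("left_clavicle", "right_clavicle", "heart", "left_lung", "right_lung")


def generate_phantom(
    config: PhantomConfig | None = None, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Generate one phantom image and its five full-shape region masks."""
    if config is None:
        config = PhantomConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    size = config.size
    geometry = _scale_geometry(config)

    masks: dict[str, np.ndarray] = {}
    for name in REGIONS:
        shape = geometry[name]
        _check_bounds(shape, size)
        masks[name] = _rasterize(shape, size).astype(np.uint8)

    # Ownership label map: each pixel belongs to exactly one region.
    owner = np.full(size, "background", dtype=object)
    for name in reversed(_PRIORITY):
        owner[masks[name] == 1] = name

    mean = np.empty(size, dtype=np.float64)
    sd = np.empty(size, dtype=np.float64)
    region_names = ["background", *REGIONS]
    for name in region_names:
        m, s = config.intensity[name]
        sel = owner == name
        mean[sel] = m
        sd[sel] = s

    image = mean + sd * rng.standard_normal(size)
    if config.noise_sd > 0.0:
        image = image + config.noise_sd * rng.standard_normal(size)
    image = np.clip(image, 0.0, 1.0)
    return image, masks


def generate_dataset(
    n: int,
    config: PhantomConfig | None = None,
    seed: int | None = None,
    out_dir: str | os.PathLike = "phantoms",
) -> list[str]:
    """Write ``n`` phantoms as PNGs under ``out_dir`` and return basenames.

    Layout: ``images/<name>.png`` plus ``masks/<region>/<name>.png`` for
    each of the five regions, and a ``manifest.csv`` listing every file.
    Deterministic (byte-identical files) for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if config is None:
        config = PhantomConfig()
    if seed is None:
        seed = config.seed
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for region in REGIONS:
        (out / "masks" / region).mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    names = []
    manifest_rows = []
    for i in range(n):
        name = f"phantom_{i:04d}"
        image, masks = generate_phantom(config, rng)
        save_image(image, out / "images" / f"{name}.png")
        for region in REGIONS:
            mask_path = Path("masks") / region / f"{name}.png"
            save_mask(masks[region], out / mask_path)
            manifest_rows.append(
                {
                    "filename": f"images/{name}.png",
                    "region": region,
                    "mask_path": str(mask_path),
                    "seed": seed,
                }
            )
        names.append(name)

    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["filename", "region", "mask_path", "seed"])
        writer.writeheader()
        writer.writerows(manifest_rows)
    return names
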