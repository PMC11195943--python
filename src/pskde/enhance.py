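"""Baseline contrast enhancement: histogram equalization and CLAHE.

Global histogram equalization (HE) maps each intensity through the
normalized cumulative distribution of the binned image histogram, which
spreads the intensity distribution over the full range.  Contrast-limited
adaptive histogram equalization (CLAHE) equalizes the image tile by tile,
clipping each tile histogram bin at a multiple of the uniform bin height
and redistributing the clipped excess over all bins before building the
tile's mapping; output pixels blend the four surrounding tile mappings
bilinearly to suppress tile-boundary artifacts.

The redistribution here is a single deterministic pass: the integer part
of the excess is spread evenly over all bins and the remainder is added
one count per bin starting from bin 0.  With a single tile and an
unbounded clip limit, CLAHE reduces to plain HE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .images import validate_image


@dataclass(frozen=True)
class ClaheConfig:
    """CLAHE parameters.

    clip_limit is a dimensionless multiple of the uniform tile bin height
    (tile pixel count / n_bins); tiles is the (rows, cols) tile grid.
    """

    clip_limit: float = 2.0
    tiles: tuple[int, int] = (8, 8)
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.clip_limit < 1.0:
            raise ValueError("invalid clip limit")
        if self.tiles[0] < 1 or self.tiles[1] < 1:
            raise ValueError("tiles must each be at least 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")


def _bin_indices(image: np.ndarray, n_bins: int) -> np.ndarray:
    """Map [0, 1] intensities to bin indices 0..n_bins-1 (1.0 in last bin)."""
    idx = np.floor(image * n_bins).astype(np.intp)
    return np.minimum(idx, n_bins - 1)


def hist_equalize(image: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Global histogram equalization via the normalized binned CDF."""
    img = validate_image(image)
    binned = _bin_indices(img, n_bins)
    hist = np.bincount(binned.ravel(), minlength=n_bins)
    cdf = np.cumsum(hist) / img.size
    return cdf[binned]


def clip_and_redistribute(hist: np.ndarray, clip_count: float) -> np.ndarray:
    """Clip a histogram at clip_count and redistribute the excess.

    Single pass: every bin gets the integer share of the excess; the
    remainder is handed out one count per bin from bin 0 upward.  The
    returned histogram has exactly the same total as the input.
    """
    hist = np.asarray(hist, dtype=np.int64)
    clip = int(np.floor(clip_count))
    clipped = np.minimum(hist, clip)
    excess = int(hist.sum() - clipped.sum())
    n_bins = hist.size
    share, remainder = divmod(excess, n_bins)
    out = clipped + share
    out[:remainder] += 1
    return out


def clahe(image: np.ndarray, config: ClaheConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The image is partitioned into a ``tiles`` grid; each tile's clipped,
    redistributed histogram defines a CDF mapping, and each output pixel
    bilinearly interpolates the mappings of the four nearest tile centers
    (clamped replication at the borders).
    """
    if config is None:
        config = ClaheConfig()
    img = validate_image(image)
    h, w = img.shape
    trows, tcols = config.tiles
    if trows > h or tcols > w:
        raise ValueError("tile grid exceeds image")
    n_bins = config.n_bins

    binned = _bin_indices(img, n_bins)

    row_edges = np.linspace(0, h, trows + 1).astype(np.intp)
    col_edges = np.linspace(0, w, tcols + 1).astype(np.intp)
    row_centers = (row_edges[:-1] + row_edges[1:] - 1) / 2.0
    col_centers = (col_edges[:-1] + col_edges[1:] - 1) / 2.0

    # Per-tile CDF lookup tables on the shared bin grid.
    luts = np.empty((trows, tcols, n_bins), dtype=np.float64)
    for ti in range(trows):
        for tj in range(tcols):
            tile = binned[row_edges[ti] : row_edges[ti + 1], col_edges[tj] : col_edges[tj + 1]]
            count = tile.size
            hist = np.bincount(tile.ravel(), minlength=n_bins)
            clip_count = config.clip_limit * count / n_bins
            hist = clip_and_redistribute(hist, clip_count)
            assert hist.sum() == count  # mass conservation
            luts[ti, tj] = np.cumsum(hist) / count

    # Bilinear blend of the four surrounding tile mappings, clamped at borders.
    ys = np.arange(h, dtype=np.float64)
    xs = np.arange(w, dtype=np.float64)
    r1 = np.clip(np.searchsorted(row_centers, ys), 0, trows - 1)
    r0 = np.clip(r1 - 1, 0, trows - 1)
    c1 = np.clip(np.searchsorted(col_centers, xs), 0, tcols - 1)
    c0 = np.clip(c1 - 1, 0, tcols - 1)

    def _weights(pos: np.ndarray, lo: np.ndarray, hi: np.ndarray, centers: np.ndarray) -> np.ndarray:
        span = centers[hi] - centers[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(span > 0, (pos - centers[lo]) / np.where(span > 0, span, 1.0), 0.0)
        return np.clip(frac, 0.0, 1.0)

    wy = _weights(ys, r0, r1, row_centers)[:, None]
    wx = _weights(xs, c0, c1, col_centers)[None, :]

    r0g, r1g = r0[:, None], r1[:, None]
    c0g, c1g = c0[None, :], c1[None, :]
    v00 = luts[r0g, c0g, binned]
    v01 = luts[r0g, c1g, binned]
    v10 = luts[r1g, c0g, binned]
    v11 = luts[r1g, c1g, binned]
    out = (
        (1 - wy) * ((1 - wx) * v00 + wx * v01)
        + wy * ((1 - wx) * v10 + wx * v11)
    )
    return np.clip(out, 0.0, 1.0)
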