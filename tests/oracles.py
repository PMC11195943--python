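"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths (and where easy,
even the numpy helpers it uses) so that agreement is a genuine
cross-check, not a tautology.
"""

import math

import numpy as np


def gaussian_sum_density(values, h, grid):
    """Raw truncated-and-renormalized Gaussian kernel density on a grid.

    Plain Python loops: density(g) = (1/(n h)) sum_i phi((g - x_i)/h),
    then divided by its own trapezoidal mass over the grid.
    """
    values = list(np.asarray(values, dtype=float).ravel())
    grid = np.asarray(grid, dtype=float)
    n = len(values)
    raw = []
    for g in grid:
        s = 0.0
        for x in values:
            z = (g - x) / h
            s += math.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
        raw.append(s / (n * h))
    # manual trapezoid
    mass = 0.0
    for i in range(len(grid) - 1):
        mass += 0.5 * (raw[i] + raw[i + 1]) * (grid[i + 1] - grid[i])
    return np.array([r / mass for r in raw])


def linear_interp(grid, table, v):
    """Piecewise-linear lookup by explicit bracketing (no np.interp)."""
    grid = np.asarray(grid, dtype=float)
    table = np.asarray(table, dtype=float)
    if v <= grid[0]:
        return float(table[0])
    if v >= grid[-1]:
        return float(table[-1])
    k = int(np.searchsorted(grid, v, side="right")) - 1
    t = (v - grid[k]) / (grid[k + 1] - grid[k])
    return float((1.0 - t) * table[k] + t * table[k + 1])


def single_tile_clahe(image, clip_limit, n_bins):
    """Brute-force clipped-histogram equalization for a single tile."""
    img = np.asarray(image, dtype=float)
    bins = np.minimum((img * n_bins).astype(int), n_bins - 1)
    hist = [0] * n_bins
    for b in bins.ravel():
        hist[b] += 1
    count = img.size
    clip = int(math.floor(clip_limit * count / n_bins))
    excess = 0
    clipped = []
    for c in hist:
        if c > clip:
            excess += c - clip
            clipped.append(clip)
        else:
            clipped.append(c)
    share, rem = divmod(excess, n_bins)
    redist = [c + share + (1 if i < rem else 0) for i, c in enumerate(clipped)]
    cdf = []
    running = 0
    for c in redist:
        running += c
        cdf.append(running / count)
    out = np.empty_like(img)
    it = np.nditer(bins, flags=["multi_index"])
    for b in it:
        out[it.multi_index] = cdf[int(b)]
    return out


def welch_by_hand(a, b):
    """Welch t and Welch–Satterthwaite df from first principles."""
    a = [float(x) for x in a]
    b = [float(x) for x in b]
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sa, sb = va / na, vb / nb
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return t, df
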