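"""Naive exhaustive-window reference implementations.

Everything here is written as directly as possible — explicit loops
over windows and offsets — so the fast implementations can be checked
against them on small rasters.  Nothing in this module may import from
colonyedge's filter internals.
"""

from __future__ import annotations

import numpy as np


def pad_edge(img: np.ndarray, r: int) -> np.ndarray:
    return np.pad(img, r, mode="edge")


def conv2d_replicate(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct correlation with edge replication (kernel must be odd-sized)."""
    kh, kw = kernel.shape
    ry, rx = kh // 2, kw // 2
    p = np.pad(img.astype(float), ((ry, ry), (rx, rx)), mode="edge")
    out = np.zeros_like(img, dtype=float)
    for dy in range(kh):
        for dx in range(kw):
            out += kernel[dy, dx] * p[dy : dy + img.shape[0], dx : dx + img.shape[1]]
    return out


def disk_offsets(radius: float) -> list[tuple[int, int]]:
    r = int(np.ceil(radius))
    return [
        (dy, dx)
        for dy in range(-r, r + 1)
        for dx in range(-r, r + 1)
        if dy * dy + dx * dx <= (radius + 0.5) ** 2
    ]


def window_values(img: np.ndarray, y: int, x: int, offsets) -> np.ndarray:
    h, w = img.shape
    vals = []
    for dy, dx in offsets:
        yy = min(max(y + dy, 0), h - 1)  # edge replication
        xx = min(max(x + dx, 0), w - 1)
        vals.append(img[yy, xx])
    return np.array(vals)


def rank_filter_naive(img: np.ndarray, radius: float, mode: str) -> np.ndarray:
    offs = disk_offsets(radius)
    out = np.zeros_like(img, dtype=float)
    fn = np.max if mode == "maximum" else np.min
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            out[y, x] = fn(window_values(img, y, x, offs))
    return out


def remove_outliers_naive(
    img: np.ndarray, radius: float, threshold: float, polarity: str
) -> np.ndarray:
    offs = disk_offsets(radius)
    out = img.astype(float).copy()
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            med = np.median(window_values(img, y, x, offs))
            dev = img[y, x] - med if polarity == "bright" else med - img[y, x]
            if dev > threshold:
                out[y, x] = med
    return out


def grey_opening_ball_naive(img: np.ndarray, radius: float) -> np.ndarray:
    """Opening with the ball-height structuring element, min/max loops."""
    r = int(np.ceil(radius))
    offs = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                offs.append((dy, dx, np.sqrt(radius * radius - d2)))
    h, w = img.shape
    ero = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            best = np.inf
            for dy, dx, z in offs:
                yy = min(max(y + dy, 0), h - 1)
                xx = min(max(x + dx, 0), w - 1)
                best = min(best, img[yy, xx] - z)
            ero[y, x] = best
    dil = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            best = -np.inf
            for dy, dx, z in offs:
                yy = min(max(y + dy, 0), h - 1)
                xx = min(max(x + dx, 0), w - 1)
                best = max(best, ero[yy, xx] + z)
            dil[y, x] = best
    return dil


def binary_dilate_naive(mask: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            if mask[y, x]:
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            out[yy, xx] = True
    return out


def binary_erode_naive(mask: np.ndarray) -> np.ndarray:
    """Erosion treating out-of-frame pixels as foreground."""
    h, w = mask.shape
    out = np.ones_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            keep = True
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < h and 0 <= xx < w and not mask[yy, xx]:
                        keep = False
            out[y, x] = keep
    return out


def close_naive(mask: np.ndarray, iterations: int) -> np.ndarray:
    out = mask.copy()
    for _ in range(iterations):
        out = binary_dilate_naive(out)
    for _ in range(iterations):
        out = binary_erode_naive(out)
    return out | mask


def fill_holes_naive(mask: np.ndarray) -> np.ndarray:
    """Flood the background from the border with 4-connectivity."""
    h, w = mask.shape
    reach = np.zeros((h, w), dtype=bool)
    stack = [
        (y, x)
        for y in range(h)
        for x in range(w)
        if (y in (0, h - 1) or x in (0, w - 1)) and not mask[y, x]
    ]
    for y, x in stack:
        reach[y, x] = True
    while stack:
        y, x = stack.pop()
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            yy, xx = y + dy, x + dx
            if 0 <= yy < h and 0 <= xx < w and not mask[yy, xx] and not reach[yy, xx]:
                reach[yy, xx] = True
                stack.append((yy, xx))
    return mask | ~reach


def edt_naive(mask: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean distance to the nearest background pixel,
    counting anything beyond the frame as background."""
    h, w = mask.shape
    bg = [(y, x) for y in range(h) for x in range(w) if not mask[y, x]]
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            d = min(y + 1, h - y, x + 1, w - x)  # frame border
            for by, bx in bg:
                d = min(d, np.hypot(y - by, x - bx))
            out[y, x] = d
    return out


def label_count_union_find(mask: np.ndarray, connectivity: int) -> int:
    h, w = mask.shape
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    if connectivity == 4:
        neigh = [(-1, 0), (0, -1)]
    else:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1)]
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            parent.setdefault((y, x), (y, x))
            for dy, dx in neigh:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and mask[yy, xx]:
                    union((y, x), (yy, xx))
    return len({find(p) for p in parent})


def quantile_rescale_naive(
    img: np.ndarray, fraction: float, white: float
) -> np.ndarray:
    flat = np.sort(img.ravel())

    def q(p):
        # linear interpolation between order statistics
        idx = p * (flat.size - 1)
        lo = int(np.floor(idx))
        hi = int(np.ceil(idx))
        return flat[lo] + (idx - lo) * (flat[hi] - flat[lo])

    lo, hi = q(fraction / 2), q(1 - fraction / 2)
    if hi <= lo:
        return img.astype(float).copy()
    return np.clip((img - lo) * white / (hi - lo), 0.0, white)


def ols_normal_equations(x: np.ndarray, y: np.ndarray):
    """Slope/intercept/R^2 straight from the normal equations."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (slope * x + intercept)
    ss_res = (resid**2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1 - ss_res / ss_tot
    return slope, intercept, r2
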