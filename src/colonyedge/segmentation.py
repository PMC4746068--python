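"""Splitting touching colonies and labelling objects.

Touching roughly-circular objects are separated by the classic binary
watershed: the Euclidean distance map of the mask is computed, seeds are
placed at its regional maxima (shallow maxima suppressed by a dynamics
tolerance, mirroring ultimate-eroded-point noise tolerance), and the
inverted distance map is flooded from the seeds.  One-pixel divide
lines between basins become background, so objects separated this way
do not share pixels.

The method is reliable for circular/elliptical regions only; elongated
or branched shapes tend to be over-split, which is why pipelines expose
the watershed as a skippable stage.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed as _skimage_watershed

from .core import BinaryMask, LabelMap, Raster

__all__ = ["distance_map", "find_seeds", "binary_watershed", "label_components"]

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


def distance_map(mask: BinaryMask) -> Raster:
    """Euclidean distance of each foreground pixel to the nearest
    background pixel; pixels beyond the frame count as background."""
    padded = np.pad(mask.pixels, 1, mode="constant", constant_values=False)
    edm = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return Raster(edm, calibration=mask.calibration, white_level=float(max(edm.max(), 1.0)))


def find_seeds(edm: Raster, tolerance: float = 0.5) -> list[tuple[int, int]]:
    """Seed coordinates (row, col), one per surviving regional maximum.

    Maxima whose dynamics (height above the saddle towards a higher
    maximum) are <= ``tolerance`` are merged into their neighbour; each
    surviving maximal plateau contributes one seed at the plateau pixel
    closest to its centroid.  Every connected foreground component gets
    at least one seed.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    labels, _ = _seed_markers(edm.pixels, tolerance)
    out: list[tuple[int, int]] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, labels.max() + 1)):
        ys, xs = np.nonzero(labels[sl] == lab)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        cy, cx = ys.mean(), xs.mean()
        k = int(np.argmin((ys - cy) ** 2 + (xs - cx) ** 2))
        out.append((int(ys[k]), int(xs[k])))
    out.sort()
    return out


def _seed_markers(edm: np.ndarray, tolerance: float) -> tuple[np.ndarray, int]:
    """Label image of seed plateaus (8-connected), one label per seed."""
    fg = edm > 0
    if not fg.any():
        return np.zeros(edm.shape, dtype=np.int32), 0
    if tolerance > 0:
        rec = reconstruction(edm - tolerance, edm, method="dilation")
    else:
        rec = edm
    peaks = local_maxima(rec, connectivity=2) & fg
    comp, n_comp = ndimage.label(fg, structure=_STRUCT_8)
    # guarantee one seed per component (a tolerance larger than a
    # component's relief can suppress all its maxima)
    for i in range(1, n_comp + 1):
        sel = comp == i
        if not peaks[sel].any():
            vals = np.where(sel, edm, -np.inf)
            peaks[np.unravel_index(int(np.argmax(vals)), edm.shape)] = True
    markers, n = ndimage.label(peaks, structure=_STRUCT_8)
    return markers.astype(np.int32), int(n)


def binary_watershed(mask: BinaryMask, tolerance: float = 0.5) -> BinaryMask:
    """Split fused convex objects along watershed divide lines.

    Floods the inverted distance map from the tolerance-merged seeds;
    divide lines between different seeds become background.  Components
    with a single seed are returned unchanged, so the component count
    never decreases and the output foreground is a subset of the input.
    """
    edm = distance_map(mask).pixels
    markers, n = _seed_markers(edm, tolerance)
    if n <= 1:
        return mask.copy()
    labels = _skimage_watershed(-edm, markers=markers, mask=mask.pixels, connectivity=2)
    # carve a one-pixel divide along basin contacts: a pixel becomes
    # background when an 8-neighbour belongs to a lower-numbered basin
    pos = np.where(labels > 0, labels, np.iinfo(np.int32).max).astype(np.int32)
    min_neigh = ndimage.minimum_filter(pos, size=3, mode="constant", cval=np.iinfo(np.int32).max)
    divide = (labels > 0) & (min_neigh < labels)
    out = mask.pixels & (labels > 0) & ~divide
    return mask.with_pixels(out)


def label_components(mask: BinaryMask, connectivity: int = 8) -> LabelMap:
    """Connected-component labelling with deterministic raster-scan order.

    Labels are assigned 1..n in order of each component's first pixel in
    raster-scan order.
    """
    if connectivity == 4:
        structure = _STRUCT_4
    elif connectivity == 8:
        structure = _STRUCT_8
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask.pixels, structure=structure)
    labels = _relabel_raster_order(labels, n)
    return LabelMap(labels.astype(np.int32), calibration=mask.calibration, n_objects=int(n))


def _relabel_raster_order(labels: np.ndarray, n: int) -> np.ndarray:
    if n == 0:
        return labels
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier raster positions overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[1 + order] = np.arange(1, n + 1)
    return remap[labels]
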