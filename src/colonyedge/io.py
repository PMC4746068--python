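"""Reading and writing images (TIFF / PNG / JPEG).

Spatial calibration is supplied by the caller (config), not read from
file metadata.  Masks are exported with the display polarity of the
original tool — objects black on a white background — while the
in-memory convention stays foreground = object.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import BinaryMask, LabelMap, Raster

__all__ = [
    "read_image",
    "read_raster",
    "write_raster",
    "write_mask",
    "write_labelmap",
    "IMAGE_SUFFIXES",
]

IMAGE_SUFFIXES = {".tif", ".tiff", ".png", ".jpg", ".jpeg"}


def read_image(path: str | Path) -> np.ndarray:
    """Read an image file as a numpy array (grayscale 2-D or RGB 3-D)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return arr


def _white_level_for(arr: np.ndarray) -> float:
    if arr.dtype == np.uint16:
        return 65535.0
    return 255.0


def read_raster(path: str | Path, calibration: float = 1.0, channel: str = "luminance") -> Raster:
    """Read an image file straight into a grayscale :class:`Raster`."""
    from .image_ops import to_grayscale

    arr = read_image(path)
    return to_grayscale(
        arr, channel, calibration=calibration, white_level=_white_level_for(arr)
    )


def write_raster(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    if raster.white_level > 255:
        arr = np.clip(np.round(raster.pixels), 0, 65535).astype(np.uint16)
    else:
        arr = np.clip(np.round(raster.pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_mask(mask: BinaryMask, path: str | Path, objects_black: bool = True) -> None:
    """Export a binary mask; by default objects are black on white."""
    arr = np.where(mask.pixels, 0, 255) if objects_black else np.where(mask.pixels, 255, 0)
    arr = arr.astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_labelmap(labels: LabelMap, path: str | Path) -> None:
    """Export a label map as a 16-bit TIFF label image."""
    if labels.n_objects > 65535:
        raise ValueError("more than 65535 objects cannot be stored in 16-bit")
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint16))
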