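"""Core raster containers.

Every processing stage consumes and produces one of three containers:

``Raster``
    A 2-D grayscale intensity grid.  Pixels are held as ``float64``
    regardless of the source bit depth; ``white_level`` records the
    nominal full-scale value of the depth the image came from (255 for
    8-bit, 65535 for 16-bit), so filters that clip or rescale know the
    valid range.  ``calibration`` is the physical size of one pixel in
    micrometres (1.0 means "uncalibrated", i.e. pixel units).

``BinaryMask``
    A foreground/background grid.  Foreground always means "object",
    independent of how a mask is displayed or exported.

``LabelMap``
    Connected components as consecutive integer labels 1..n with 0 as
    background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "BinaryMask", "LabelMap"]


@dataclass
class Raster:
    pixels: np.ndarray
    calibration: float = 1.0
    white_level: float = 255.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("Raster requires a 2-D pixel grid with width, height >= 1")
        if not np.all(np.isfinite(px)):
            raise ValueError("Raster intensities must be finite")
        if not self.calibration > 0:
            raise ValueError("calibration must be > 0")
        if not self.white_level > 0:
            raise ValueError("white_level must be > 0")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Raster":
        """New raster with the same calibration/depth but different pixels."""
        return Raster(pixels, calibration=self.calibration, white_level=self.white_level)

    def copy(self) -> "Raster":
        return self.with_pixels(self.pixels.copy())


@dataclass
class BinaryMask:
    pixels: np.ndarray
    calibration: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("BinaryMask requires a 2-D pixel grid")
        if px.dtype != bool:
            uniq = np.unique(px)
            if not np.all(np.isin(uniq, (0, 1))) and not np.all(
                np.isin(uniq, (0, np.max(uniq) if uniq.size else 0))
            ):
                raise ValueError("BinaryMask pixels must have exactly two states")
            px = px > 0
        if not self.calibration > 0:
            raise ValueError("calibration must be > 0")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "BinaryMask":
        return BinaryMask(pixels, calibration=self.calibration)

    def copy(self) -> "BinaryMask":
        return self.with_pixels(self.pixels.copy())


@dataclass
class LabelMap:
    labels: np.ndarray
    calibration: float = 1.0
    n_objects: int = field(default=-1)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("LabelMap requires a 2-D label grid")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("labels must be integers")
        if lab.size and lab.min() < 0:
            raise ValueError("labels must be non-negative")
        n = int(lab.max()) if lab.size else 0
        present = np.unique(lab[lab > 0])
        if present.size != n or (present.size and present[-1] != n):
            raise ValueError("labels must be consecutive 1..n")
        if self.n_objects == -1:
            self.n_objects = n
        elif self.n_objects != n:
            raise ValueError("n_objects inconsistent with label grid")
        if not self.calibration > 0:
            raise ValueError("calibration must be > 0")
        self.labels = lab

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def mask(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, calibration=self.calibration)
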