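"""Object filtering and measurement ("analyze particles").

Each labelled object yields a :class:`ParticleRecord` with calibrated
area and perimeter, circularity, centroid, bounding box, an
edge-contact flag and — when a redirect image is supplied — mean and
integrated intensity measured on that image over the object's pixels.

Perimeter follows the traced-outline convention: the outer contour of
the object is walked as a Freeman chain code (orthogonal step = 1,
diagonal step = sqrt(2)) and the step lengths are summed.  Inner
contours of holes are ignored, and holes count towards the area, so
pipelines should fill holes before measuring.  Circularity is
4*pi*area/perimeter^2, capped at 1.0 (single pixels and dominoes would
otherwise exceed it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelMap, Raster

__all__ = [
    "ParticleRecord",
    "ParticleFilter",
    "measure_particles",
    "filter_particles",
    "summarize",
    "records_to_dataframe",
    "chain_code_perimeter",
]


@dataclass(frozen=True)
class ParticleRecord:
    id: int
    area: float                      # calibrated units^2 (um^2 if calibrated)
    perimeter: float                 # calibrated length
    circularity: float               # in [0, 1]
    centroid: tuple[float, float]    # (x, y) in pixels
    bbox: tuple[int, int, int, int]  # (x0, y0, width, height) in pixels
    touches_edge: bool
    area_px: float = 0.0             # raw pixel count
    mean_intensity: float | None = None
    integrated_intensity: float | None = None

    def __post_init__(self):
        if self.id < 1:
            raise ValueError("id must be a positive integer")
        if not self.area > 0:
            raise ValueError("area must be > 0")
        if not (0.0 <= self.circularity <= 1.0):
            raise ValueError("circularity must be in [0, 1]")
        x0, y0, w, h = self.bbox
        cx, cy = self.centroid
        if not (x0 <= cx <= x0 + w and y0 <= cy <= y0 + h):
            raise ValueError("bbox must contain centroid")


@dataclass(frozen=True)
class ParticleFilter:
    """Size/shape/edge acceptance window for detected objects.

    Size bounds are in the calibrated area units of the run (um^2 when a
    um/px calibration is set, px^2 otherwise).
    """

    min_size: float = 0.0
    max_size: float = math.inf
    min_circularity: float = 0.0
    max_circularity: float = 1.0
    exclude_edges: bool = False

    def __post_init__(self):
        if self.min_size > self.max_size:
            raise ValueError("min_size must be <= max_size")
        if self.min_circularity > self.max_circularity:
            raise ValueError("min_circularity must be <= max_circularity")
        for c in (self.min_circularity, self.max_circularity):
            if not (0.0 <= c <= 1.0):
                raise ValueError("circularity bounds must be in [0, 1]")

    def accepts(self, rec: ParticleRecord) -> bool:
        return (
            self.min_size <= rec.area <= self.max_size
            and self.min_circularity <= rec.circularity <= self.max_circularity
            and not (self.exclude_edges and rec.touches_edge)
        )


# Moore neighbourhood in clockwise order starting East; step lengths
# alternate 1 (orthogonal) and sqrt(2) (diagonal).
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_STEP_LEN = [1.0, math.sqrt(2)] * 4


def chain_code_perimeter(obj: np.ndarray) -> float:
    """Chain-code length of the outer contour of a connected object.

    ``obj`` is a boolean array containing a single 8-connected object.
    The boundary is traced through pixel centres (Moore neighbour
    tracing with Jacob's stopping criterion); a single pixel has no
    steps and returns 0.
    """
    ys, xs = np.nonzero(obj)
    if ys.size <= 1:
        return 0.0
    pad = np.pad(obj, 1, mode="constant", constant_values=False)
    # start at the first pixel in raster-scan order; its West neighbour
    # and the whole row above it are guaranteed background
    start = (int(ys.min()) + 1, int(xs[ys == ys.min()].min()) + 1)
    cur = start
    back = (start[0], start[1] - 1)  # backtrack: last background examined
    first: tuple | None = None
    perim = 0.0
    max_steps = 8 * ys.size + 16
    for _ in range(max_steps):
        bd = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        d = -1
        for k in range(8):
            dk = (bd + k) % 8
            ny, nx = cur[0] + _MOORE[dk][0], cur[1] + _MOORE[dk][1]
            if pad[ny, nx]:
                d = dk
                break
            back = (ny, nx)
        if d == -1:  # safety net; cannot happen for a 2+ pixel object
            return perim
        if first is None:
            first = (cur, d)
        elif (cur, d) == first:  # Jacob's stopping criterion
            return perim
        perim += _STEP_LEN[d]
        cur = (ny, nx)
    return perim


def _perimeters(labels: np.ndarray, n: int, slices) -> np.ndarray:
    out = np.zeros(n + 1)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        if sl is None:
            continue
        out[lab] = chain_code_perimeter(labels[sl] == lab)
    return out


def measure_particles(
    labels: LabelMap,
    redirect: Raster | None = None,
    calibration: float | None = None,
) -> list[ParticleRecord]:
    """Measure every labelled object.

    ``redirect`` supplies the intensity image (typically the original,
    unprocessed image) over which mean/integrated intensity are taken.
    ``calibration`` overrides the label map's own um/px scale.
    """
    if redirect is not None and redirect.shape != labels.shape:
        raise ValueError("redirect image dimensions must match the label map")
    cal = labels.calibration if calibration is None else calibration
    if not cal > 0:
        raise ValueError("calibration must be > 0")
    lab = labels.labels
    n = labels.n_objects
    if n == 0:
        return []
    slices = ndimage.find_objects(lab, max_label=n)
    perims = _perimeters(lab, n, slices)
    h, w = lab.shape
    records: list[ParticleRecord] = []
    for i in range(1, n + 1):
        sl = slices[i - 1]
        obj = lab[sl] == i
        area_px = float(obj.sum())
        ys, xs = np.nonzero(obj)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        cx, cy = float(xs.mean()), float(ys.mean())
        x0, y0 = int(xs.min()), int(ys.min())
        bw, bh = int(xs.max()) - x0 + 1, int(ys.max()) - y0 + 1
        perim_px = perims[i]
        if perim_px > 0:
            circ = min(1.0, 4.0 * math.pi * area_px / perim_px**2)
        else:
            circ = 1.0  # sub-resolution object: treat as circular
        touches = x0 == 0 or y0 == 0 or x0 + bw == w or y0 + bh == h
        mean_i = integ_i = None
        if redirect is not None:
            vals = redirect.pixels[ys, xs]
            mean_i = float(vals.mean())
            integ_i = float(vals.sum())
        records.append(
            ParticleRecord(
                id=i,
                area=area_px * cal * cal,
                perimeter=perim_px * cal,
                circularity=circ,
                centroid=(cx, cy),
                bbox=(x0, y0, bw, bh),
                touches_edge=touches,
                area_px=area_px,
                mean_intensity=mean_i,
                integrated_intensity=integ_i,
            )
        )
    return records


def filter_particles(
    records: list[ParticleRecord], f: ParticleFilter
) -> list[ParticleRecord]:
    """Keep records inside the filter's size/circularity/edge window,
    preserving order; surviving records are the input objects unchanged."""
    return [r for r in records if f.accepts(r)]


def summarize(records: list[ParticleRecord]) -> dict:
    """Count and location/scale statistics of the detected objects."""
    n = len(records)
    if n == 0:
        return {"n": 0, "defined": False}
    areas = np.array([r.area for r in records])
    perims = np.array([r.perimeter for r in records])
    q1, med, q3 = np.percentile(areas, [25, 50, 75])
    return {
        "n": n,
        "defined": True,
        "mean_area": float(areas.mean()),
        "median_area": float(med),
        "q1_area": float(q1),
        "q3_area": float(q3),
        "mean_perimeter": float(perims.mean()),
        "median_perimeter": float(np.median(perims)),
    }


_CSV_COLUMNS = [
    "image",
    "id",
    "area",
    "perimeter",
    "circularity",
    "x",
    "y",
    "bbox_x",
    "bbox_y",
    "bbox_w",
    "bbox_h",
    "touches_edge",
    "mean_intensity",
    "integrated_intensity",
]


def records_to_dataframe(records: list[ParticleRecord], image: str = "") -> pd.DataFrame:
    """One row per particle with a fixed, documented column set."""
    rows = []
    for r in records:
        rows.append(
            {
                "image": image,
                "id": r.id,
                "area": r.area,
                "perimeter": r.perimeter,
                "circularity": r.circularity,
                "x": r.centroid[0],
                "y": r.centroid[1],
                "bbox_x": r.bbox[0],
                "bbox_y": r.bbox[1],
                "bbox_w": r.bbox[2],
                "bbox_h": r.bbox[3],
                "touches_edge": r.touches_edge,
                "mean_intensity": r.mean_intensity,
                "integrated_intensity": r.integrated_intensity,
            }
        )
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)
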