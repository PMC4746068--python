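"""Folder-level batch processing and overlay rendering.

Every readable image in a folder is processed with the same pipeline
configuration; a per-image particle CSV, a combined CSV and (optionally)
overlay images with detected outlines and id labels are written.  A
failing image is logged and skipped rather than aborting the batch, so
one corrupt file does not cost the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy import ndimage

from .core import LabelMap, Raster
from .io import IMAGE_SUFFIXES, read_raster
from .particle_analysis import records_to_dataframe
from .pipeline import PipelineConfig, run_pipeline

__all__ = ["BatchResult", "run_batch", "render_overlay"]

logger = logging.getLogger("colonyedge")


@dataclass
class BatchResult:
    per_image: pd.DataFrame          # one row per input file: path, n, stats, status
    combined: pd.DataFrame           # concatenated particle table
    failures: list[tuple[str, str]]  # (path, error message)
    results: dict = field(default_factory=dict)  # path -> PipelineResult

    @property
    def n_images(self) -> int:
        return len(self.per_image)


def run_batch(
    folder: str | Path,
    cfg: PipelineConfig,
    out: str | Path | None = None,
    *,
    overlays: bool = False,
    keep_results: bool = False,
) -> BatchResult:
    """Process every image in ``folder`` with one configuration.

    Non-image files are ignored with a warning.  Outputs (per-image
    CSVs, combined CSV, optional overlay PNGs and final masks) go to
    ``out`` when given.
    """
    folder = Path(folder)
    files = sorted(p for p in folder.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    skipped = [p for p in sorted(folder.iterdir()) if p.is_file() and p.suffix.lower() not in IMAGE_SUFFIXES]
    for p in skipped:
        logger.warning("ignoring non-image file %s", p.name)
    if not files:
        raise ValueError(f"no readable images in {folder}")
    out_dir = Path(out) if out is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    tables = []
    failures: list[tuple[str, str]] = []
    results: dict = {}
    for path in files:
        try:
            raster = read_raster(path, calibration=cfg.calibration)
            result = run_pipeline(raster, cfg)
        except Exception as exc:  # noqa: BLE001 - a bad file must not kill the batch
            logger.warning("failed on %s: %s", path.name, exc)
            failures.append((str(path), str(exc)))
            rows.append({"image": path.name, "n": 0, "status": f"failed: {exc}"})
            continue
        logger.info(
            "%s: %d particles with pipeline %s", path.name, result.n_particles, cfg.name
        )
        table = records_to_dataframe(result.particles, image=path.name)
        tables.append(table)
        summ = result.summary
        rows.append(
            {
                "image": path.name,
                "n": result.n_particles,
                "mean_area": summ.get("mean_area", float("nan")),
                "median_area": summ.get("median_area", float("nan")),
                "status": "ok",
            }
        )
        if keep_results:
            results[str(path)] = result
        if out_dir is not None:
            table.to_csv(out_dir / f"{path.stem}.particles.csv", index=False)
            if overlays:
                render_overlay(
                    raster,
                    result.labels,
                    out_dir / f"{path.stem}.overlay.png",
                    only_ids=[r.id for r in result.particles],
                )
    combined = (
        pd.concat(tables, ignore_index=True)
        if tables
        else records_to_dataframe([], image="")
    )
    per_image = pd.DataFrame(rows)
    if out_dir is not None:
        combined.to_csv(out_dir / "combined.particles.csv", index=False)
        per_image.to_csv(out_dir / "per_image.csv", index=False)
    return BatchResult(per_image=per_image, combined=combined, failures=failures, results=results)


def _boundary(mask: np.ndarray) -> np.ndarray:
    er = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    return mask & ~er


def render_overlay(
    image: Raster,
    labels: LabelMap,
    out: str | Path,
    only_ids: list[int] | None = None,
    color: tuple[int, int, int] = (255, 0, 0),
) -> Path:
    """Write the original image with object outlines and id labels burned in.

    Outline pixels are the objects' inner boundary pixels.  ``only_ids``
    restricts the overlay to the listed labels (e.g. the particles that
    survived filtering).
    """
    if image.shape != labels.shape:
        raise ValueError("image and label map dimensions must match")
    scale = 255.0 / image.white_level
    base = np.clip(image.pixels * scale, 0, 255).astype(np.uint8)
    rgb = np.stack([base] * 3, axis=-1)
    ids = (
        list(range(1, labels.n_objects + 1))
        if only_ids is None
        else [i for i in only_ids if 1 <= i <= labels.n_objects]
    )
    lab = labels.labels
    slices = ndimage.find_objects(lab, max_label=labels.n_objects)
    label_pos = []
    for i in ids:
        sl = slices[i - 1]
        if sl is None:
            continue
        obj = lab[sl] == i
        by, bx = np.nonzero(_boundary(obj))
        rgb[by + sl[0].start, bx + sl[1].start] = color
        if by.size:
            label_pos.append((i, float(bx.mean() + sl[1].start), float(by.mean() + sl[0].start)))
    pil = Image.fromarray(rgb)
    draw = ImageDraw.Draw(pil)
    for i, cx, cy in label_pos:
        draw.text((cx + 2, cy + 2), str(i), fill=color)
    out = Path(out)
    pil.save(out)
    return out
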