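"""Configurable edge-detection pipeline and its presets.

A pipeline is an ordered list of named, parameterised stages applied to
a grayscale raster.  The canonical order is the six-step edge-detection recipe:

1. background subtraction,
2. sharpening/enhancing and Sobel edge detection,
3. Gaussian smoothing and automatic binarization,
4. closing and hole filling (optionally repeated around a maximum /
   minimum cycle that bridges broken edges),
5. denoising (remove outliers) and watershed segmentation,
6. filtering and measuring particles.

Stages can be disabled individually: skipping the watershed avoids
over-splitting of non-circular objects, and skipping the fill keeps
open structures (e.g. tube networks) unfilled.  Presets capture the
parameter sets used for the three assay classes plus a plain
thresholding baseline for comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import image_ops, segmentation
from .core import BinaryMask, LabelMap, Raster
from .particle_analysis import (
    ParticleFilter,
    ParticleRecord,
    filter_particles,
    measure_particles,
    summarize,
)

__all__ = [
    "StageSpec",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "preset",
    "PRESET_NAMES",
    "toggle_stage",
    "sweep_parameters",
    "save_config",
    "load_config",
]


# name -> (callable, input kind, output kind); kinds: raster / binary /
# any (polymorphic) / convert (raster -> binary)
_STAGES: dict[str, tuple] = {
    "subtract_background": (image_ops.subtract_background, "raster", "raster"),
    "invert": (image_ops.invert, "raster", "raster"),
    "sharpen": (image_ops.sharpen, "raster", "raster"),
    "enhance_contrast": (image_ops.enhance_contrast, "raster", "raster"),
    "sobel_edges": (image_ops.sobel_edges, "raster", "raster"),
    "gaussian_blur": (image_ops.gaussian_blur, "any", "same"),
    "make_binary": (image_ops.make_binary, "convert", "binary"),
    "morphological_close": (image_ops.morphological_close, "binary", "binary"),
    "fill_holes": (image_ops.fill_holes, "binary", "binary"),
    "rank_filter": (image_ops.rank_filter, "any", "same"),
    "remove_outliers": (image_ops.remove_outliers, "any", "same"),
    "binary_watershed": (segmentation.binary_watershed, "binary", "binary"),
}


@dataclass(frozen=True)
class StageSpec:
    name: str
    params: dict = field(default_factory=dict)
    enabled: bool = True

    def __post_init__(self):
        if self.name not in _STAGES:
            raise ValueError(
                f"unknown stage {self.name!r}; registered stages: {sorted(_STAGES)}"
            )


@dataclass(frozen=True)
class PipelineConfig:
    stages: tuple[StageSpec, ...]
    calibration: float = 1.0
    filter: ParticleFilter = field(default_factory=ParticleFilter)
    light_background: bool = False
    redirect_to_original: bool = True
    name: str = "custom"

    def __post_init__(self):
        object.__setattr__(self, "stages", tuple(self.stages))
        if not self.calibration > 0:
            raise ValueError("calibration must be > 0")

    def enabled_stages(self) -> tuple[StageSpec, ...]:
        return tuple(s for s in self.stages if s.enabled)

    def validate(self) -> None:
        """Reject configurations whose enabled stages are mis-ordered:
        binary operations must come after make_binary, grayscale-only
        operations before it."""
        state = "raster"
        for s in self.enabled_stages():
            _, kind, out = _STAGES[s.name]
            if kind == "raster" and state != "raster":
                raise ValueError(f"grayscale stage {s.name!r} after binarization")
            if kind == "binary" and state != "binary":
                raise ValueError(f"binary stage {s.name!r} before make_binary")
            if kind == "convert":
                if state != "raster":
                    raise ValueError("make_binary applied twice")
                state = "binary"
            elif out != "same":
                state = out
        if state != "binary":
            raise ValueError("pipeline must binarize the image (enable make_binary)")

    # ---- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        f = self.filter
        return {
            "name": self.name,
            "calibration": self.calibration,
            "light_background": self.light_background,
            "redirect_to_original": self.redirect_to_original,
            "filter": {
                "min_size": f.min_size,
                "max_size": f.max_size,
                "min_circularity": f.min_circularity,
                "max_circularity": f.max_circularity,
                "exclude_edges": f.exclude_edges,
            },
            "stages": [
                {"name": s.name, "params": dict(s.params), "enabled": s.enabled}
                for s in self.stages
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        filt = d.get("filter", {})
        max_size = filt.get("max_size", math.inf)
        if isinstance(max_size, str):
            max_size = math.inf
        return cls(
            stages=tuple(
                StageSpec(s["name"], dict(s.get("params", {})), bool(s.get("enabled", True)))
                for s in d["stages"]
            ),
            calibration=float(d.get("calibration", 1.0)),
            filter=ParticleFilter(
                min_size=float(filt.get("min_size", 0.0)),
                max_size=float(max_size),
                min_circularity=float(filt.get("min_circularity", 0.0)),
                max_circularity=float(filt.get("max_circularity", 1.0)),
                exclude_edges=bool(filt.get("exclude_edges", False)),
            ),
            light_background=bool(d.get("light_background", False)),
            redirect_to_original=bool(d.get("redirect_to_original", True)),
            name=str(d.get("name", "custom")),
        )


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    mask: BinaryMask                       # final binary image
    labels: LabelMap                       # all connected components
    particles: list[ParticleRecord]        # records surviving the filter
    all_particles: list[ParticleRecord]    # records before filtering
    diagnostics: dict                      # stage name -> intermediate (on request)
    summary: dict

    @property
    def n_particles(self) -> int:
        return len(self.particles)


def run_pipeline(
    image: Raster, cfg: PipelineConfig, keep_diagnostics: bool = False
) -> PipelineResult:
    """Apply the enabled stages in order, then label, measure and filter.

    The stage order is validated before any computation.  With
    ``keep_diagnostics`` every intermediate raster/mask is retained
    under ``"<index>:<stage name>"`` keys.  Intensity measurements are
    redirected to the original (input) image when the config says so.
    """
    cfg.validate()
    original = Raster(image.pixels, calibration=cfg.calibration, white_level=image.white_level)
    current: Raster | BinaryMask = original.copy()
    diagnostics: dict = {}
    for i, s in enumerate(cfg.stages):
        if not s.enabled:
            continue
        func, kind, _ = _STAGES[s.name]
        params = dict(s.params)
        if s.name == "subtract_background" and "light_background" not in params:
            params["light_background"] = cfg.light_background
        current = func(current, **params)
        if keep_diagnostics:
            diagnostics[f"{i}:{s.name}"] = current.copy()
    mask: BinaryMask = current
    labels = segmentation.label_components(mask, connectivity=8)
    redirect = original if cfg.redirect_to_original else None
    all_records = measure_particles(labels, redirect=redirect, calibration=cfg.calibration)
    records = filter_particles(all_records, cfg.filter)
    return PipelineResult(
        mask=mask,
        labels=labels,
        particles=records,
        all_particles=all_records,
        diagnostics=diagnostics,
        summary=summarize(records),
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "tumorsphere",
    "bacterial",
    "clonogenic",
    "fluorescent_nuclei",
    "threshold_baseline",
)

# Remove-outliers deviation threshold on the 8-bit scale; presets name
# only a radius, so all of them share this default.
_OUTLIER_THRESHOLD = 50.0


def _edge_head(enhance: float = 0.002) -> list[StageSpec]:
    # sharpening + contrast enhancement applied before the Sobel step
    return [
        StageSpec("sharpen"),
        StageSpec("enhance_contrast", {"saturated_fraction": enhance}),
        StageSpec("sobel_edges"),
    ]


def preset(name: str, calibration: float | None = None) -> PipelineConfig:
    """Named parameter sets for the supported assay classes.

    tumorsphere
        dark spheroids in brightfield: rolling ball radius 80, Gaussian
        sigma 2, maximum r=2 / minimum r=3 edge-bridging cycle, remove
        outliers r=12, size filter 50-Infinity (calibrated units^2),
        circularity 0.2-1.
    bacterial
        small bright plate colonies: scratch removal (remove outliers
        r=2, bright) in place of background subtraction, Gaussian sigma
        1, no maximum/minimum cycle, size filter 2-Infinity.
    clonogenic
        stained colonies: rolling ball radius 50, Gaussian sigma 0.5,
        remove outliers r=2 then maximum 1 / minimum 4 and remove
        outliers r=5, size filter 50-Infinity.
    fluorescent_nuclei
        bright nuclei on dark background (split one channel first).
    threshold_baseline
        plain global-threshold + watershed comparator without the edge
        detection head.
    """
    if name == "tumorsphere":
        cfg = PipelineConfig(
            stages=(
                StageSpec("subtract_background", {"radius": 80}),
                *_edge_head(),
                StageSpec("gaussian_blur", {"sigma": 2}),
                StageSpec("make_binary"),
                StageSpec("morphological_close", {"iterations": 1}),
                StageSpec("fill_holes"),
                StageSpec("rank_filter", {"radius": 2, "mode": "maximum"}),
                StageSpec("morphological_close", {"iterations": 1}),
                StageSpec("fill_holes"),
                StageSpec("rank_filter", {"radius": 3, "mode": "minimum"}),
                StageSpec(
                    "remove_outliers",
                    {"radius": 12, "threshold": _OUTLIER_THRESHOLD, "polarity": "bright"},
                ),
                StageSpec("binary_watershed", {"tolerance": 0.5}),
            ),
            calibration=1.0,
            filter=ParticleFilter(min_size=50.0, min_circularity=0.2, max_circularity=1.0),
            light_background=True,
            name="tumorsphere",
        )
    elif name == "bacterial":
        cfg = PipelineConfig(
            stages=(
                StageSpec(
                    "remove_outliers",
                    {"radius": 2, "threshold": _OUTLIER_THRESHOLD, "polarity": "bright"},
                ),
                *_edge_head(),
                StageSpec("gaussian_blur", {"sigma": 1}),
                StageSpec("make_binary"),
                StageSpec("morphological_close", {"iterations": 1}),
                StageSpec("fill_holes"),
                StageSpec("binary_watershed", {"tolerance": 0.5}),
            ),
            calibration=1.0,
            filter=ParticleFilter(min_size=2.0, min_circularity=0.2, max_circularity=1.0),
            light_background=False,
            name="bacterial",
        )
    elif name == "clonogenic":
        cfg = PipelineConfig(
            stages=(
                StageSpec("subtract_background", {"radius": 50}),
                *_edge_head(),
                StageSpec("gaussian_blur", {"sigma": 0.5}),
                StageSpec(
                    "remove_outliers",
                    {"radius": 2, "threshold": _OUTLIER_THRESHOLD, "polarity": "bright"},
                ),
                StageSpec("make_binary"),
                StageSpec("morphological_close", {"iterations": 1}),
                StageSpec("fill_holes"),
                StageSpec("rank_filter", {"radius": 1, "mode": "maximum"}),
                StageSpec("morphological_close", {"iterations": 1}),
                StageSpec("fill_holes"),
                StageSpec("rank_filter", {"radius": 4, "mode": "minimum"}),
                StageSpec(
                    "remove_outliers",
                    {"radius": 5, "threshold": _OUTLIER_THRESHOLD, "polarity": "bright"},
                ),
                StageSpec("binary_watershed", {"tolerance": 0.5}),
            ),
            calibration=1.0,
            filter=ParticleFilter(min_size=50.0, min_circularity=0.2, max_circularity=1.0),
            light_background=True,
            name="clonogenic",
        )
    elif name == "fluorescent_nuclei":
        cfg = PipelineConfig(
            stages=(
                StageSpec("subtract_background", {"radius": 25}),
                *_edge_head(),
                StageSpec("gaussian_blur", {"sigma": 1}),
                StageSpec("make_binary"),
                StageSpec("morphological_close", {"iterations": 1}),
                StageSpec("fill_holes"),
                StageSpec("binary_watershed", {"tolerance": 0.5}),
            ),
            calibration=1.0,
            filter=ParticleFilter(min_size=10.0, min_circularity=0.0, max_circularity=1.0),
            light_background=False,
            name="fluorescent_nuclei",
        )
    elif name == "threshold_baseline":
        cfg = PipelineConfig(
            stages=(
                StageSpec("subtract_background", {"radius": 50}),
                StageSpec("invert"),
                StageSpec("make_binary"),
                StageSpec("binary_watershed", {"tolerance": 0.5}),
            ),
            calibration=1.0,
            filter=ParticleFilter(min_size=50.0, min_circularity=0.3, max_circularity=1.0),
            light_background=True,
            name="threshold_baseline",
        )
    else:
        raise ValueError(f"unknown preset {name!r}; valid names: {PRESET_NAMES}")
    if calibration is not None:
        cfg = replace(cfg, calibration=calibration)
    return cfg


def toggle_stage(cfg: PipelineConfig, stage: str, enabled: bool) -> PipelineConfig:
    """Return a config with every stage of the given name enabled or
    disabled; the original config is unmodified."""
    if not any(s.name == stage for s in cfg.stages):
        raise ValueError(f"stage {stage!r} not present in this pipeline")
    stages = tuple(
        replace(s, enabled=enabled) if s.name == stage else s for s in cfg.stages
    )
    return replace(cfg, stages=stages)


# ---------------------------------------------------------------------------
# parameter sweep
# ---------------------------------------------------------------------------


def _apply_override(cfg: PipelineConfig, key: str, value) -> PipelineConfig:
    target, _, param = key.partition(".")
    if not param:
        raise ValueError(f"override key {key!r} must look like 'stage.param'")
    if target == "filter":
        return replace(cfg, filter=replace(cfg.filter, **{param: value}))
    if target == "config":
        return replace(cfg, **{param: value})
    if not any(s.name == target for s in cfg.stages):
        raise ValueError(f"stage {target!r} not present in this pipeline")
    stages = tuple(
        replace(s, params={**s.params, param: value}) if s.name == target else s
        for s in cfg.stages
    )
    return replace(cfg, stages=stages)


def sweep_parameters(
    image: Raster,
    base: PipelineConfig,
    grid: dict,
    truth,
    max_centroid_distance: float = 10.0,
) -> pd.DataFrame:
    """Rank pipeline configurations by detection F1 against ground truth.

    ``grid`` maps override keys ('stage.param', 'filter.param' or
    'config.param') to value lists; the cartesian product is evaluated
    in given order.  ``truth`` is a GroundTruth or a list of reference
    ParticleRecord.  The result table is sorted by F1 (descending) with
    ties broken by grid order, which makes the ranking deterministic.
    """
    from .evaluation import match_objects

    if not grid:
        raise ValueError("grid must be non-empty")
    if hasattr(truth, "to_records"):
        reference = truth.to_records(base.calibration)
    else:
        reference = list(truth)
    if not reference:
        raise ValueError("truth must contain at least one reference object")
    keys = list(grid.keys())
    rows = []
    for idx, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        cfg = base
        for k, v in zip(keys, combo):
            cfg = _apply_override(cfg, k, v)
        result = run_pipeline(image, cfg)
        match = match_objects(result.particles, reference, max_centroid_distance)
        row = {k: v for k, v in zip(keys, combo)}
        row.update(
            {
                "grid_index": idx,
                "f1": match.f1(),
                "n_detected": len(result.particles),
                "n_matched": len(match.pairs),
            }
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(["f1", "grid_index"], ascending=[False, True], kind="stable")
    return df.reset_index(drop=True)
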