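import numpy as np
import pytest

from colonyedge.core import BinaryMask, Raster
from colonyedge.particle_analysis import ParticleFilter
from colonyedge.pipeline import PipelineConfig, StageSpec


def random_raster(rng: np.random.Generator, max_side: int = 24) -> Raster:
    h = int(rng.integers(3, max_side + 1))
    w = int(rng.integers(3, max_side + 1))
    return Raster(rng.integers(0, 256, size=(h, w)).astype(float))


def random_mask(rng: np.random.Generator, max_side: int = 24, p: float = 0.4) -> BinaryMask:
    h = int(rng.integers(3, max_side + 1))
    w = int(rng.integers(3, max_side + 1))
    return BinaryMask(rng.random((h, w)) < p)


def disk_mask(h: int, w: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


def despeckling_config() -> PipelineConfig:
    """Edge pipeline tuned for speck/scratch-ridden bright-colony plates:
    bacterial-style head plus a post-fill outlier-removal pass and a size
    filter above the speck scale."""
    return PipelineConfig(
        stages=(
            StageSpec("remove_outliers", {"radius": 2, "threshold": 50, "polarity": "bright"}),
            StageSpec("sharpen"),
            StageSpec("enhance_contrast", {"saturated_fraction": 0.002}),
            StageSpec("sobel_edges"),
            StageSpec("gaussian_blur", {"sigma": 1}),
            StageSpec("make_binary"),
            StageSpec("morphological_close", {"iterations": 1}),
            StageSpec("fill_holes"),
            StageSpec("remove_outliers", {"radius": 8, "threshold": 50, "polarity": "bright"}),
            StageSpec("binary_watershed", {"tolerance": 0.5}),
        ),
        filter=ParticleFilter(min_size=300.0, min_circularity=0.2),
        light_background=False,
        name="despeckling",
    )
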