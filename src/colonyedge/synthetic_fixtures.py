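"""Synthetic colony scenes with exact ground truth.

The generator emulates the image classes the pipeline is meant for:

* tumorsphere-like — a dozen dark, roughly elliptical spheroids of very
  different sizes on a light, low-contrast background with a smooth
  illumination gradient;
* bacterial-like — many small bright colonies on a dark plate with
  scratch-line artifacts;
* clonogenic-like — stained (high-contrast dark) colonies of moderate
  size;
* touching pairs — two fused disks, the hard case for the watershed;
* artifact stress — a field of sub-colony specks and scratches around a
  few genuine colonies.

Objects are anti-aliased ellipses (1 px edge softness) composited over
a background level, with optional linear illumination gradient, radial
vignette, Gaussian sensor noise, speck and scratch artifacts.  The
analytic area pi*a*b of each ellipse is the ground truth that detected
areas are scored against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Raster

__all__ = [
    "EllipseSpec",
    "SceneSpec",
    "GroundTruth",
    "generate_scene",
    "scenario",
    "write_fixture_folder",
    "SCENARIO_NAMES",
]


@dataclass(frozen=True)
class EllipseSpec:
    cx: float
    cy: float
    a: float                 # semi-axis along `orientation`, px
    b: float                 # perpendicular semi-axis, px
    orientation: float = 0.0  # radians
    contrast: float = 40.0    # amplitude above/below background, > 0
    dark: bool = True         # dark object on light background?

    @property
    def true_area(self) -> float:
        return math.pi * self.a * self.b

    @property
    def equivalent_radius(self) -> float:
        return math.sqrt(self.a * self.b)


@dataclass(frozen=True)
class SceneSpec:
    width: int = 512
    height: int = 512
    objects: tuple[EllipseSpec, ...] = ()
    background_level: float = 180.0
    gradient: tuple[float, float] = (0.0, 0.0)   # (gx, gy): intensity change across full frame
    vignette: float = 0.0                        # radial darkening amplitude at the corners
    noise_sigma: float = 0.0
    n_specks: int = 0
    speck_area: tuple[int, int] = (1, 4)         # px, inclusive range
    speck_contrast: float = 40.0
    n_scratches: int = 0
    scratch_length: tuple[int, int] = (60, 200)
    scratch_width: float = 1.5
    scratch_contrast: float = 35.0
    touching_pairs: bool = False                 # overlapping objects allowed
    calibration: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for o in self.objects:
            if not (0 <= o.cx < self.width and 0 <= o.cy < self.height):
                raise ValueError("object centres must lie inside the frame")
            if o.contrast <= 0:
                raise ValueError("contrast amplitudes must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    ids: tuple[int, ...]
    centers: tuple[tuple[float, float], ...]   # (x, y)
    areas: tuple[float, ...]                    # analytic pi*a*b, px^2
    equivalent_radii: tuple[float, ...]
    dark: tuple[bool, ...]
    artifact_mask: np.ndarray = field(repr=False, default=None)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "x": [c[0] for c in self.centers],
                "y": [c[1] for c in self.centers],
                "area": self.areas,
                "equivalent_radius": self.equivalent_radii,
                "dark": self.dark,
            }
        )

    def to_records(self, calibration: float = 1.0):
        """Reference particle records for the evaluation module."""
        from .particle_analysis import ParticleRecord

        recs = []
        for i, (c, a, r) in enumerate(zip(self.centers, self.areas, self.equivalent_radii)):
            recs.append(
                ParticleRecord(
                    id=self.ids[i],
                    area=a * calibration * calibration,
                    perimeter=2 * math.pi * r * calibration,
                    circularity=1.0,
                    centroid=c,
                    bbox=(
                        int(c[0] - r) , int(c[1] - r),
                        int(2 * r) + 1, int(2 * r) + 1,
                    ),
                    touches_edge=False,
                    area_px=a,
                )
            )
        return recs


def _ellipse_coverage(spec: EllipseSpec, width: int, height: int) -> np.ndarray:
    """Anti-aliased coverage in [0, 1] with ~1 px edge softness."""
    r_max = max(spec.a, spec.b) + 2
    x0 = max(int(spec.cx - r_max), 0)
    x1 = min(int(spec.cx + r_max) + 2, width)
    y0 = max(int(spec.cy - r_max), 0)
    y1 = min(int(spec.cy + r_max) + 2, height)
    cov = np.zeros((height, width))
    if x0 >= x1 or y0 >= y1:
        return cov
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - spec.cx
    dy = yy - spec.cy
    ct, st = math.cos(spec.orientation), math.sin(spec.orientation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    rho = np.sqrt((u / spec.a) ** 2 + (v / spec.b) ** 2)
    # approximate signed distance to the boundary in pixels
    sd = (rho - 1.0) * min(spec.a, spec.b)
    cov[y0:y1, x0:x1] = np.clip(0.5 - sd, 0.0, 1.0)
    return cov


def generate_scene(spec: SceneSpec) -> tuple[Raster, GroundTruth]:
    """Render a scene and its ground truth; deterministic for a given seed."""
    if not spec.touching_pairs:
        for i, oi in enumerate(spec.objects):
            for oj in spec.objects[i + 1 :]:
                d = math.hypot(oi.cx - oj.cx, oi.cy - oj.cy)
                if d < 0.9 * (max(oi.a, oi.b) + max(oj.a, oj.b)):
                    raise ValueError(
                        "overlapping objects are only allowed in touching-pairs mode"
                    )
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    img = np.full((h, w), float(spec.background_level))

    # illumination field
    gx, gy = spec.gradient
    if gx or gy:
        xr = np.linspace(0.0, 1.0, w)[None, :]
        yr = np.linspace(0.0, 1.0, h)[:, None]
        img = img + gx * xr + gy * yr
    if spec.vignette:
        yy, xx = np.mgrid[0:h, 0:w]
        r2 = ((xx - w / 2) / (w / 2)) ** 2 + ((yy - h / 2) / (h / 2)) ** 2
        img = img - spec.vignette * r2 / 2.0

    # objects; touching pairs composite by max coverage so the fused
    # union has no intensity ridge between the two disks
    if spec.touching_pairs:
        dark_cov = np.zeros((h, w))
        bright_cov = np.zeros((h, w))
        for o in spec.objects:
            cov = _ellipse_coverage(o, w, h)
            if o.dark:
                dark_cov = np.maximum(dark_cov, cov * o.contrast)
            else:
                bright_cov = np.maximum(bright_cov, cov * o.contrast)
        img = img - dark_cov + bright_cov
    else:
        for o in spec.objects:
            cov = _ellipse_coverage(o, w, h)
            img = img + (o.contrast if not o.dark else -o.contrast) * cov

    artifact = np.zeros((h, w), dtype=bool)

    # speck artifacts: tiny square-ish blobs of 1..speck_area[1] pixels
    for _ in range(spec.n_specks):
        area = int(rng.integers(spec.speck_area[0], spec.speck_area[1] + 1))
        sy = int(rng.integers(1, h - 2))
        sx = int(rng.integers(1, w - 2))
        sign = -1.0 if rng.random() < 0.5 else 1.0
        py, px = sy, sx
        for _k in range(area):
            img[py, px] += sign * spec.speck_contrast
            artifact[py, px] = True
            step = rng.integers(0, 4)
            py = int(np.clip(py + (step == 0) - (step == 1), 0, h - 1))
            px = int(np.clip(px + (step == 2) - (step == 3), 0, w - 1))

    # scratch lines
    for _ in range(spec.n_scratches):
        length = int(rng.integers(spec.scratch_length[0], spec.scratch_length[1] + 1))
        theta = rng.uniform(0, math.pi)
        cx = rng.uniform(0.1 * w, 0.9 * w)
        cy = rng.uniform(0.1 * h, 0.9 * h)
        t = np.linspace(-length / 2, length / 2, length * 2)
        lx = np.clip(np.round(cx + t * math.cos(theta)).astype(int), 0, w - 1)
        ly = np.clip(np.round(cy + t * math.sin(theta)).astype(int), 0, h - 1)
        width_px = max(int(round(spec.scratch_width)), 1)
        for ox in range(width_px):
            img[ly, np.clip(lx + ox, 0, w - 1)] += spec.scratch_contrast
            artifact[ly, np.clip(lx + ox, 0, w - 1)] = True

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.round(np.clip(img, 0.0, 255.0))

    truth = GroundTruth(
        ids=tuple(range(1, len(spec.objects) + 1)),
        centers=tuple((o.cx, o.cy) for o in spec.objects),
        areas=tuple(o.true_area for o in spec.objects),
        equivalent_radii=tuple(o.equivalent_radius for o in spec.objects),
        dark=tuple(o.dark for o in spec.objects),
        artifact_mask=artifact,
    )
    return Raster(img, calibration=spec.calibration, white_level=255.0), truth


# ---------------------------------------------------------------------------
# named scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = (
    "tumorsphere_like",
    "bacterial_like",
    "clonogenic_like",
    "touching_pairs",
    "artifact_stress",
)


def _place_objects(
    rng: np.random.Generator,
    n: int,
    w: int,
    h: int,
    radius_range: tuple[float, float],
    *,
    dark: bool,
    contrast_range: tuple[float, float],
    aspect_max: float = 1.0,
    margin: float = 12.0,
    max_tries: int = 20000,
) -> tuple[EllipseSpec, ...]:
    objs: list[EllipseSpec] = []
    tries = 0
    while len(objs) < n and tries < max_tries:
        tries += 1
        a = rng.uniform(*radius_range)
        b = a / rng.uniform(1.0, aspect_max) if aspect_max > 1.0 else a
        r = max(a, b)
        cx = rng.uniform(r + margin, w - r - margin)
        cy = rng.uniform(r + margin, h - r - margin)
        ok = True
        for o in objs:
            if math.hypot(cx - o.cx, cy - o.cy) < r + max(o.a, o.b) + margin:
                ok = False
                break
        if ok:
            objs.append(
                EllipseSpec(
                    cx=cx,
                    cy=cy,
                    a=a,
                    b=b,
                    orientation=rng.uniform(0, math.pi),
                    contrast=rng.uniform(*contrast_range),
                    dark=dark,
                )
            )
    if len(objs) < n:
        raise RuntimeError("could not place the requested objects without overlap")
    return tuple(objs)


def scenario(name: str, seed: int = 0) -> SceneSpec:
    """A documented SceneSpec for one of the named image classes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC01]))
    if name == "tumorsphere_like":
        # 12 dark low-contrast spheroids, radii 10-60 px, 10% illumination
        # gradient, mild sensor noise, a few debris specks
        w, h = 800, 640
        objs = _place_objects(
            rng, 12, w, h, (12, 60), dark=True, contrast_range=(15, 40),
            aspect_max=1.35, margin=18.0,
        )
        return SceneSpec(
            width=w, height=h, objects=objs, background_level=190.0,
            gradient=(12.0, 7.0), vignette=6.0, noise_sigma=2.0,
            n_specks=6, speck_area=(1, 3), speck_contrast=30.0,
            calibration=1.3, seed=seed,
        )
    if name == "bacterial_like":
        # 22 small bright colonies on a dark plate plus scratch marks
        w, h = 512, 512
        objs = _place_objects(
            rng, 22, w, h, (2.5, 6.0), dark=False, contrast_range=(45, 70),
            margin=10.0,
        )
        return SceneSpec(
            width=w, height=h, objects=objs, background_level=70.0,
            gradient=(6.0, 4.0), noise_sigma=2.0,
            n_scratches=5, scratch_contrast=30.0, scratch_width=1.0,
            n_specks=8, speck_area=(1, 2), speck_contrast=25.0,
            calibration=1.0, seed=seed,
        )
    if name == "clonogenic_like":
        # stained colonies: moderate size, strong contrast
        w, h = 640, 640
        objs = _place_objects(
            rng, 30, w, h, (5, 14), dark=True, contrast_range=(60, 110),
            aspect_max=1.2, margin=10.0,
        )
        return SceneSpec(
            width=w, height=h, objects=objs, background_level=200.0,
            gradient=(8.0, 5.0), noise_sigma=2.0,
            n_specks=10, speck_area=(1, 3), speck_contrast=40.0,
            calibration=1.0, seed=seed,
        )
    if name == "touching_pairs":
        # one fused pair per scene: centre distance 1.2-1.6 x radius
        w, h = 220, 180
        r = float(rng.uniform(14, 20))
        d = r * float(rng.uniform(1.2, 1.6))
        theta = float(rng.uniform(0, math.pi))
        cx, cy = w / 2, h / 2
        dx, dy = d / 2 * math.cos(theta), d / 2 * math.sin(theta)
        contrast = float(rng.uniform(35, 55))
        objs = (
            EllipseSpec(cx - dx, cy - dy, r, r, 0.0, contrast, dark=True),
            EllipseSpec(cx + dx, cy + dy, r, r, 0.0, contrast, dark=True),
        )
        return SceneSpec(
            width=w, height=h, objects=objs, background_level=190.0,
            noise_sigma=1.5, touching_pairs=True, calibration=1.0, seed=seed,
        )
    if name == "artifact_stress":
        # a handful of genuine colonies drowned in specks and scratches
        w, h = 640, 640
        objs = _place_objects(
            rng, 8, w, h, (15, 25), dark=False, contrast_range=(50, 70),
            margin=26.0,
        )
        return SceneSpec(
            width=w, height=h, objects=objs, background_level=80.0,
            gradient=(5.0, 3.0), noise_sigma=1.5,
            n_specks=520, speck_area=(1, 3), speck_contrast=45.0,
            n_scratches=5, scratch_contrast=30.0, scratch_width=1.0,
            calibration=1.0, seed=seed,
        )
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")


def write_fixture_folder(
    folder: str | Path, scenario_name: str, n_images: int, seed: int = 0
) -> list[Path]:
    """Write ``n_images`` scene TIFFs with truth CSVs side by side."""
    from .io import write_raster

    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(n_images):
        spec = scenario(scenario_name, seed=seed + i)
        raster, truth = generate_scene(spec)
        img_path = folder / f"{scenario_name}_{i:03d}.tif"
        write_raster(raster, img_path)
        df = truth.to_dataframe()
        df.insert(0, "image", img_path.name)
        df.to_csv(img_path.with_suffix(".truth.csv"), index=False)
        paths.append(img_path)
    return paths
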