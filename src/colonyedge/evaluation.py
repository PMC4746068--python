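"""Comparing detected objects against a reference (manual) object table.

The comparison protocol pairs each reference object with at most one
detected object by centroid proximity and then handles the two failure
modes of automated counting explicitly:

* split rule — if a reference colony was fragmented into several
  detected pieces, the largest piece is the match and the remaining
  fragments are counted as extra detected objects;
* merge rule — if two touching reference colonies were detected as one
  object, the merged detection is matched to the larger reference and
  the smaller reference counts as undetected.

Agreement between matched measurements is summarised by an ordinary
least-squares fit of detected vs reference values (slope, intercept,
R^2) plus the mean absolute per-pair deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .particle_analysis import ParticleRecord

__all__ = ["MatchResult", "AgreementSummary", "match_objects", "agreement", "replicate_average"]


@dataclass(frozen=True)
class MatchResult:
    pairs: tuple[tuple[int, int], ...]          # (reference id, detected id)
    extra_detected: tuple[int, ...]             # detected ids counted as additional objects
    undetected_reference: tuple[int, ...]       # reference ids with no match
    area_deviation: tuple[float, ...]           # per pair: detected - reference area
    perimeter_deviation: tuple[float, ...]
    extra_ids: dict = field(default_factory=dict)  # detected id -> additional colony number
    reference: tuple = field(default=(), repr=False)
    detected: tuple = field(default=(), repr=False)

    @property
    def n_reference(self) -> int:
        return len(self.pairs) + len(self.undetected_reference)

    @property
    def n_detected(self) -> int:
        return len(self.pairs) + len(self.extra_detected)

    def f1(self) -> float:
        tp = len(self.pairs)
        fp = len(self.extra_detected)
        fn = len(self.undetected_reference)
        denom = 2 * tp + fp + fn
        return 2 * tp / denom if denom else 0.0


def match_objects(
    detected: list[ParticleRecord],
    reference: list[ParticleRecord],
    max_centroid_distance: float = 10.0,
) -> MatchResult:
    """Greedy centroid-proximity assignment with split/merge handling.

    References are processed in descending area order (ties by id).  A
    detected object is a candidate for a reference when their centroid
    distance is at most max(reference equivalent radius,
    ``max_centroid_distance``); the largest-area unassigned candidate
    wins.  Unassigned detections become extra objects and are given new
    sequential colony numbers after the last reference id; unmatched
    references are reported as undetected.
    """
    if not max_centroid_distance > 0:
        raise ValueError("max_centroid_distance must be > 0")
    ref_order = sorted(reference, key=lambda r: (-r.area, r.id))
    assigned: set[int] = set()
    pairs: list[tuple[int, int]] = []
    area_dev: list[float] = []
    perim_dev: list[float] = []
    undetected: list[int] = []
    for ref in ref_order:
        # equivalent radius from the calibrated area in pixel units when
        # available; fall back to the calibrated area
        r_px = math.sqrt((ref.area_px if ref.area_px > 0 else ref.area) / math.pi)
        reach = max(r_px, max_centroid_distance)
        candidates = [
            d
            for d in detected
            if d.id not in assigned
            and math.hypot(d.centroid[0] - ref.centroid[0], d.centroid[1] - ref.centroid[1])
            <= reach
        ]
        if not candidates:
            undetected.append(ref.id)
            continue
        best = max(candidates, key=lambda d: (d.area, -d.id))
        assigned.add(best.id)
        pairs.append((ref.id, best.id))
        area_dev.append(best.area - ref.area)
        perim_dev.append(best.perimeter - ref.perimeter)
    extras = [d.id for d in detected if d.id not in assigned]
    next_id = max((r.id for r in reference), default=0) + 1
    extra_ids = {}
    for did in extras:
        extra_ids[did] = next_id
        next_id += 1
    pairs_sorted = sorted(pairs)
    order = [pairs.index(p) for p in pairs_sorted]
    return MatchResult(
        pairs=tuple(pairs_sorted),
        extra_detected=tuple(extras),
        undetected_reference=tuple(sorted(undetected)),
        area_deviation=tuple(area_dev[i] for i in order),
        perimeter_deviation=tuple(perim_dev[i] for i in order),
        extra_ids=extra_ids,
        reference=tuple(reference),
        detected=tuple(detected),
    )


@dataclass(frozen=True)
class AgreementSummary:
    slope: float
    intercept: float
    r_squared: float
    mean_absolute_deviation: float
    n_ref: int
    n_det: int
    n_pairs: int
    fit_defined: bool = True


def agreement(result: MatchResult, measure: str = "area") -> AgreementSummary:
    """OLS of the detected measure on the reference measure over matched
    pairs, plus the mean absolute per-pair deviation."""
    if measure not in ("area", "perimeter"):
        raise ValueError("measure must be 'area' or 'perimeter'")
    ref_by_id = {r.id: r for r in result.reference}
    det_by_id = {d.id: d for d in result.detected}
    xs = np.array([getattr(ref_by_id[rid], measure) for rid, _ in result.pairs])
    ys = np.array([getattr(det_by_id[did], measure) for _, did in result.pairs])
    mad = float(np.mean(np.abs(ys - xs))) if len(xs) else float("nan")
    if len(xs) < 2 or np.allclose(xs, xs[0]):
        return AgreementSummary(
            slope=float("nan"),
            intercept=float("nan"),
            r_squared=float("nan"),
            mean_absolute_deviation=mad,
            n_ref=result.n_reference,
            n_det=result.n_detected,
            n_pairs=len(xs),
            fit_defined=False,
        )
    fit = stats.linregress(xs, ys)
    return AgreementSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        mean_absolute_deviation=mad,
        n_ref=result.n_reference,
        n_det=result.n_detected,
        n_pairs=len(xs),
    )


def replicate_average(runs: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-object mean and standard error across repeated measurement runs.

    Every run must contain the same object ids (column ``id``); value
    columns are averaged per object.  Deterministic pipelines yield a
    standard error of zero.  A single run has SE 0 by convention.
    """
    if not runs:
        raise ValueError("runs must be non-empty")
    ids0 = sorted(runs[0]["id"].tolist())
    for r in runs[1:]:
        if sorted(r["id"].tolist()) != ids0:
            raise ValueError("runs are misaligned: object ids differ between runs")
    value_cols = [
        c for c in runs[0].columns if c != "id" and pd.api.types.is_numeric_dtype(runs[0][c])
    ]
    frames = [r.set_index("id")[value_cols].sort_index() for r in runs]
    stacked = np.stack([f.to_numpy(dtype=float) for f in frames])
    mean = stacked.mean(axis=0)
    n = stacked.shape[0]
    if n > 1:
        se = stacked.std(axis=0, ddof=1) / math.sqrt(n)
    else:
        se = np.zeros_like(mean)
    out = pd.DataFrame(mean, index=frames[0].index, columns=value_cols)
    for j, c in enumerate(value_cols):
        out[f"{c}_se"] = se[:, j]
    return out.reset_index()
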