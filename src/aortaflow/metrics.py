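"""Volume-overlap and surface-distance agreement metrics.

Dice and Jaccard compare valve-pixel sets pooled over all frames of a case.
Hausdorff (HD) and average symmetric surface distance (ASSD) operate on
surface plots: a valve pixel belongs to the surface iff at least one of its
4-neighbors is non-valve (the frame border counts as non-valve).  HD is
summarized per case as the maximum over frames, ASSD as the mean over
frames; both aggregations are configurable since pooled-3D variants exist.

Empty-mask convention: both masks empty -> overlap 1.0 (perfect vacuous
agreement); exactly one empty -> overlap 0.0 and distances undefined
(NaN sentinel, with a warning), since a surface distance to an empty set
has no value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import AlignmentError, SegmentationMap

__all__ = [
    "MetricReport",
    "dice",
    "jaccard",
    "extract_surface",
    "hausdorff",
    "assd",
    "evaluate_case",
    "summarize",
    "bootstrap_ci",
    "reports_to_csv",
    "reports_to_json",
]


@dataclass(frozen=True)
class MetricReport:
    """Per-case agreement metrics between two segmentations."""

    per_case_id: str
    dice: float
    jaccard: float
    hausdorff_mm: float
    assd_mm: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "case_id": self.per_case_id,
            "dice": self.dice,
            "jaccard": self.jaccard,
            "hausdorff_mm": self.hausdorff_mm,
            "assd_mm": self.assd_mm,
        }


def _binary_stacks(a: SegmentationMap, b: SegmentationMap) -> tuple[np.ndarray, np.ndarray]:
    if a.masks.shape != b.masks.shape:
        raise AlignmentError(f"mask shapes differ: {a.masks.shape} vs {b.masks.shape}")
    return a.masks.astype(bool), b.masks.astype(bool)


def dice(a: SegmentationMap, b: SegmentationMap) -> float:
    """Dice coefficient 2|A∩B| / (|A|+|B|), pooled over frames; both empty -> 1."""
    am, bm = _binary_stacks(a, b)
    na, nb = int(am.sum()), int(bm.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((am & bm).sum()) / (na + nb)


def jaccard(a: SegmentationMap, b: SegmentationMap) -> float:
    """Jaccard index |A∩B| / |A∪B|, pooled over frames; both empty -> 1."""
    am, bm = _binary_stacks(a, b)
    union = int((am | bm).sum())
    if union == 0:
        return 1.0
    return int((am & bm).sum()) / union


def extract_surface(frame: np.ndarray) -> np.ndarray:
    """Surface plot of one binary frame.

    A valve pixel is kept iff its 4-neighborhood contains a non-valve pixel;
    the frame border counts as non-valve, so valve pixels touching the edge
    are always surface.  Equivalently: zero any valve pixel with no
    neighboring non-valve pixel.
    """
    m = np.asarray(frame).astype(bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return (m & ~interior).astype(np.uint8)


def _surface_points(frame: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    rr, cc = np.nonzero(extract_surface(frame))
    pts = np.column_stack([rr * spacing[0], cc * spacing[1]])
    return pts


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Nearest-neighbor distance from each src surface point to dst's surface."""
    tree = cKDTree(dst)
    d, _ = tree.query(src, k=1)
    return np.atleast_1d(d)


def _frame_surface_distances(
    fa: np.ndarray, fb: np.ndarray, spacing: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray] | None:
    pa = _surface_points(fa, spacing)
    pb = _surface_points(fb, spacing)
    if len(pa) == 0 and len(pb) == 0:
        return None  # vacuous frame, skipped
    if len(pa) == 0 or len(pb) == 0:
        warnings.warn(
            "one mask has no valve pixels in a frame where the other does; "
            "surface distance undefined for that frame",
            RuntimeWarning,
            stacklevel=3,
        )
        return (np.array([np.nan]), np.array([np.nan]))
    return (_directed_distances(pa, pb), _directed_distances(pb, pa))


def _iter_frame_distances(a, b, pixel_spacing_mm):
    am, bm = _binary_stacks(a, b)
    spacing = (float(pixel_spacing_mm[0]), float(pixel_spacing_mm[1]))
    for fa, fb in zip(am, bm):
        pair = _frame_surface_distances(fa, fb, spacing)
        if pair is not None:
            yield pair


def hausdorff(
    a: SegmentationMap,
    b: SegmentationMap,
    pixel_spacing_mm: Sequence[float] = (1.0, 1.0),
    aggregate: str = "max",
) -> float:
    """Symmetric Hausdorff distance in mm.

    Per frame: max over both directions of the largest nearest-neighbor
    surface distance.  Per case: the maximum over frames by default
    (``aggregate='mean'`` for the averaged variant).  Returns NaN if either
    mask is empty wherever the other is not, or if no frame has any surface.
    """
    per_frame = [
        max(float(np.max(dab)), float(np.max(dba)))
        for dab, dba in _iter_frame_distances(a, b, pixel_spacing_mm)
    ]
    if not per_frame:
        warnings.warn("no frames with valve pixels; Hausdorff undefined", RuntimeWarning)
        return float("nan")
    arr = np.asarray(per_frame)
    if np.isnan(arr).any():
        return float("nan")
    return float(arr.max() if aggregate == "max" else arr.mean())


def assd(
    a: SegmentationMap,
    b: SegmentationMap,
    pixel_spacing_mm: Sequence[float] = (1.0, 1.0),
    aggregate: str = "mean",
) -> float:
    """Average symmetric surface distance in mm.

    Per frame: mean of all nearest-neighbor distances taken in both
    directions.  Per case: mean over frames by default.
    """
    per_frame = [
        float(np.concatenate([dab, dba]).mean())
        for dab, dba in _iter_frame_distances(a, b, pixel_spacing_mm)
    ]
    if not per_frame:
        warnings.warn("no frames with valve pixels; ASSD undefined", RuntimeWarning)
        return float("nan")
    arr = np.asarray(per_frame)
    if np.isnan(arr).any():
        return float("nan")
    return float(arr.mean() if aggregate == "mean" else arr.max())


def evaluate_case(
    pred: SegmentationMap,
    truth: SegmentationMap,
    pixel_spacing_mm: Sequence[float] = (1.0, 1.0),
    case_id: str = "case",
) -> MetricReport:
    """All four agreement metrics for one case."""
    return MetricReport(
        per_case_id=case_id,
        dice=dice(pred, truth),
        jaccard=jaccard(pred, truth),
        hausdorff_mm=hausdorff(pred, truth, pixel_spacing_mm),
        assd_mm=assd(pred, truth, pixel_spacing_mm),
    )


def bootstrap_ci(
    values: Sequence[float],
    n_resamples: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Nonparametric percentile bootstrap CI for the mean of per-case values."""
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        return (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(n_resamples, vals.size))
    means = vals[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return (float(lo), float(hi))


def summarize(
    reports: Iterable[MetricReport],
    n_resamples: int = 2000,
    seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Mean and bootstrap CI per metric, in the style 'Dice = mean [lo-hi]'."""
    reports = list(reports)
    out: dict[str, dict[str, float]] = {}
    for name in ("dice", "jaccard", "hausdorff_mm", "assd_mm"):
        vals = [getattr(r, name) for r in reports]
        finite = [v for v in vals if np.isfinite(v)]
        lo, hi = bootstrap_ci(vals, n_resamples=n_resamples, seed=seed)
        out[name] = {
            "mean": float(np.mean(finite)) if finite else float("nan"),
            "ci_lo": lo,
            "ci_hi": hi,
            "n": len(finite),
        }
    return out


def format_summary(summary: dict[str, dict[str, float]]) -> str:
    labels = {
        "dice": "Dice",
        "jaccard": "Jaccard",
        "hausdorff_mm": "HD (mm)",
        "assd_mm": "ASSD (mm)",
    }
    lines = []
    for key, label in labels.items():
        s = summary[key]
        lines.append(f"{label} = {s['mean']:.3f} [CI {s['ci_lo']:.3f}-{s['ci_hi']:.3f}]")
    return "\n".join(lines)


def reports_to_csv(reports: Iterable[MetricReport], path: str | Path) -> Path:
    import pandas as pd

    path = Path(path)
    pd.DataFrame([r.as_dict() for r in reports]).to_csv(path, index=False)
    return path


def reports_to_json(reports: Iterable[MetricReport], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([r.as_dict() for r in reports], indent=2))
    return path
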