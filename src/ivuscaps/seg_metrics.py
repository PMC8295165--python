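"""Segmentation evaluation: Dice overlap and boundary-distance metrics.

Masks are integer label images with three classes: 0 background
(adventitia and surrounding tissue), 1 vessel wall (intima + media) and
2 lumen.  Distances are computed between class *boundary* pixels as a
measure of edge alignment; a config flag switches to filled-region mode
for sensitivity checks.

The average Hausdorff distance between point sets A and B is

    d_H_ave = max( mean_{a in A} min_{b in B} d(a, b),
                   mean_{b in B} min_{a in A} d(a, b) )

with the Euclidean distance d; the mean makes it far less sensitive to
single outlier pixels than the ordinary (max-based) Hausdorff distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CLASS_NAMES", "PointSet", "MetricReport",
    "dice", "extract_boundary", "hausdorff", "average_hausdorff",
    "evaluate_case", "report_rows",
]

CLASS_NAMES = {0: "background", 1: "vessel_wall", 2: "lumen"}
FOREGROUND_CLASSES = (1, 2)


@dataclass
class PointSet:
    """Pixel-center coordinates (row, col) with optional physical spacing."""

    points: np.ndarray                      # [n, 2] float
    spacing: float | None = None            # mm per pixel

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.shape[-1] != 2:
            raise ValueError("points must be (row, col) pairs")

    def __len__(self):
        return self.points.shape[0]


@dataclass
class ClassMetrics:
    dice: float                              # percent
    hausdorff_px: float | None = None
    average_hausdorff_px: float | None = None
    hausdorff_mm: float | None = None
    average_hausdorff_mm: float | None = None
    distances_missing: bool = False          # class absent from a mask


@dataclass
class MetricReport:
    """Per-class segmentation metrics for one case."""

    per_class: dict[int, ClassMetrics] = field(default_factory=dict)
    spacing: float | None = None


def _validate_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def dice(pred, truth, cls: int) -> float:
    """Dice coefficient of one class in percent.

    ``100 * 2|X ∩ Y| / (|X| + |Y|)``; when the class is absent from both
    masks the agreement is perfect and 100 is returned.
    """
    if cls not in CLASS_NAMES:
        raise ValueError(f"unknown class {cls}")
    pred, truth = _validate_pair(pred, truth)
    x = pred == cls
    y = truth == cls
    total = int(x.sum()) + int(y.sum())
    if total == 0:
        return 100.0
    return 100.0 * 2.0 * int((x & y).sum()) / total


def extract_boundary(mask, cls: int, spacing: float | None = None) -> PointSet:
    """Boundary pixels of one class, row-major ordered.

    A pixel belongs to the boundary if it has the class and at least one of
    its four neighbours does not (pixels on the image border count as
    adjacent to outside).
    """
    mask = np.asarray(mask)
    inside = mask == cls
    padded = np.pad(inside, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    rows, cols = np.nonzero(inside & ~interior)
    return PointSet(np.stack([rows, cols], axis=1).astype(float), spacing)


def _as_points(x) -> np.ndarray:
    if isinstance(x, PointSet):
        return x.points
    return PointSet(x).points


def _directed_stats(a: np.ndarray, b: np.ndarray):
    """Nearest-neighbour distances from every point of a to the set b."""
    tree = cKDTree(b)
    d, _ = tree.query(a, k=1)
    return d


def average_hausdorff(a, b) -> float:
    """Average Hausdorff distance: max of the two directed mean
    nearest-neighbour Euclidean distances.  Undefined for empty sets."""
    pa, pb = _as_points(a), _as_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("average Hausdorff distance is undefined for empty sets")
    return float(max(_directed_stats(pa, pb).mean(),
                     _directed_stats(pb, pa).mean()))


def hausdorff(a, b) -> float:
    """Ordinary Hausdorff distance: max of the two directed max-min
    Euclidean distances.  Undefined for empty sets."""
    pa, pb = _as_points(a), _as_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("Hausdorff distance is undefined for empty sets")
    return float(max(_directed_stats(pa, pb).max(),
                     _directed_stats(pb, pa).max()))


def evaluate_case(pred, truth, spacing: float | None = None,
                  boundary: bool = True,
                  classes=FOREGROUND_CLASSES) -> MetricReport:
    """Full per-class report for one predicted/reference mask pair.

    Distances are computed on class boundaries (default) or filled regions;
    mm values are px values scaled by ``spacing``.  A class missing from
    either mask yields Dice by its both-empty convention and flagged-missing
    distances (rather than infinities).
    """
    pred, truth = _validate_pair(pred, truth)
    report = MetricReport(spacing=spacing)
    for cls in classes:
        cm = ClassMetrics(dice=dice(pred, truth, cls))
        if boundary:
            pa = extract_boundary(pred, cls)
            pb = extract_boundary(truth, cls)
        else:
            pr, pc = np.nonzero(pred == cls)
            tr, tc = np.nonzero(truth == cls)
            pa = PointSet(np.stack([pr, pc], axis=1).astype(float))
            pb = PointSet(np.stack([tr, tc], axis=1).astype(float))
        if len(pa) == 0 or len(pb) == 0:
            cm.distances_missing = True
        else:
            cm.hausdorff_px = hausdorff(pa, pb)
            cm.average_hausdorff_px = average_hausdorff(pa, pb)
            if spacing is not None:
                cm.hausdorff_mm = cm.hausdorff_px * spacing
                cm.average_hausdorff_mm = cm.average_hausdorff_px * spacing
        report.per_class[cls] = cm
    return report


def report_rows(report: MetricReport, case: str = "") -> list[dict]:
    """Flatten a report to one row per (case, class, metric, units)."""
    rows = []
    for cls, cm in report.per_class.items():
        name = CLASS_NAMES.get(cls, str(cls))
        rows.append({"case": case, "class": name, "metric": "dice",
                     "units": "percent", "value": cm.dice})
        for metric, units in (("hausdorff", "px"), ("average_hausdorff", "px"),
                              ("hausdorff", "mm"), ("average_hausdorff", "mm")):
            value = getattr(cm, f"{metric}_{units}")
            if value is not None or units == "px":
                rows.append({"case": case, "class": name, "metric": metric,
                             "units": units, "value": value})
    return rows
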