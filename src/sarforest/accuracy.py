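"""Map accuracy assessment against labeled reference polygons.

Reference data are homogeneous land-cover polygons (regions of interest,
ROIs) digitized in map coordinates. They are rasterized onto the map grid
with the pixel-center-in-polygon rule, a predicted×reference confusion
matrix is tabulated, and the standard summary statistics are derived:
producer's accuracy (1 − omission error, per reference class), user's
accuracy (1 − commission error, per mapped class) and overall accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .classify import CLASS_CODES, CLASS_NAMES
from .grids import GridTransform

__all__ = [
    "ROISet",
    "ConfusionMatrix",
    "rasterize_rois",
    "confusion_matrix",
    "producer_accuracy",
    "user_accuracy",
    "overall_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass
class ROISet:
    """Labeled reference polygons in map coordinates.

    ``polygons`` is a list of ``(geometry, class_label, id)`` tuples; labels
    must come from the classifier legend. Listed order matters: where
    polygons overlap, the last-listed one wins during rasterization.
    """

    polygons: list
    crs: str = "local"

    def __post_init__(self):
        for geom, label, roi_id in self.polygons:
            if not isinstance(geom, BaseGeometry) or geom.is_empty or not geom.is_valid:
                raise ValueError(f"ROI {roi_id!r}: geometry must be valid and non-empty")
            if label not in CLASS_CODES or label == "nodata":
                raise ValueError(f"ROI {roi_id!r}: unknown class label {label!r}")

    def __len__(self):
        return len(self.polygons)


def rasterize_rois(rois: ROISet, shape, transform: GridTransform) -> np.ndarray:
    """Burn ROI class codes onto a grid using the pixel-center rule.

    A pixel gets a polygon's class iff its center point falls strictly
    inside the polygon; everywhere else is 0 (nodata). Overlapping polygons
    resolve to the last one listed (with a warning). Raises ``ValueError``
    if no pixel center falls in any polygon.
    """
    nrow, ncol = shape
    out = np.zeros(shape, dtype=np.uint8)
    px = transform.pixel_size_m
    claimed = np.zeros(shape, dtype=bool)
    overlap_warned = False
    for geom, label, roi_id in rois.polygons:
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(int(np.floor((minx - transform.x0) / px - 0.5)), 0)
        c1 = min(int(np.ceil((maxx - transform.x0) / px - 0.5)) + 1, ncol)
        r0 = max(int(np.floor((transform.y0 - maxy) / px - 0.5)), 0)
        r1 = min(int(np.ceil((transform.y0 - miny) / px - 0.5)) + 1, nrow)
        if c1 <= c0 or r1 <= r0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        x, y = transform.pixel_center(rr, cc)
        inside = shapely.contains_xy(geom, x.ravel(), y.ravel()).reshape(rr.shape)
        if not overlap_warned and np.any(claimed[r0:r1, c0:c1] & inside):
            warnings.warn("overlapping ROIs: last-listed polygon wins", stacklevel=2)
            logger.warning("overlapping ROIs detected; last-listed polygon wins")
            overlap_warned = True
        out[r0:r1, c0:c1][inside] = CLASS_CODES[label]
        claimed[r0:r1, c0:c1] |= inside
    if not claimed.any():
        raise ValueError("no ROI covers any pixel center of the template grid")
    return out


@dataclass
class ConfusionMatrix:
    """Predicted×reference pixel counts (rows = predicted, cols = reference)."""

    counts: np.ndarray
    legend: dict = field(
        default_factory=lambda: {c: CLASS_NAMES[c] for c in sorted(CLASS_NAMES) if c != 0}
    )

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.legend)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k} to match the legend")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be non-negative")

    @property
    def class_names(self) -> list:
        return [self.legend[c] for c in sorted(self.legend)]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = self.class_names
        return pd.DataFrame(self.counts, index=names, columns=names)

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("predicted").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        legend = {i + 1: name for i, name in enumerate(df.columns)}
        return cls(counts=df.to_numpy(dtype=np.int64), legend=legend)

    def summary(self) -> pd.DataFrame:
        """Per-class producer's/user's accuracy plus totals, NaN where undefined."""
        rows = []
        for i, name in enumerate(self.class_names):
            code = sorted(self.legend)[i]
            rows.append(
                {
                    "class": name,
                    "reference_total": int(self.counts[:, i].sum()),
                    "predicted_total": int(self.counts[i, :].sum()),
                    "producer_acc_pct": producer_accuracy(self, code),
                    "user_acc_pct": user_accuracy(self, code),
                }
            )
        return pd.DataFrame(rows)


def _code_index(cm: ConfusionMatrix, k) -> int:
    codes = sorted(cm.legend)
    if isinstance(k, str):
        names = {v: c for c, v in cm.legend.items()}
        if k not in names:
            raise KeyError(f"unknown class {k!r}")
        k = names[k]
    if k not in cm.legend:
        raise KeyError(f"unknown class code {k}")
    return codes.index(k)


def confusion_matrix(predicted: np.ndarray, reference: np.ndarray, n_classes: int = 4,
                     legend: dict | None = None) -> ConfusionMatrix:
    """Tabulate predicted vs reference codes over jointly labeled pixels.

    Pixels where either grid is 0 (nodata/unlabeled) are excluded. Raises
    ``ValueError`` when no pixel carries both labels.
    """
    pred = np.asarray(predicted)
    ref = np.asarray(reference)
    if pred.shape != ref.shape:
        raise ValueError("predicted and reference grids must be co-registered")
    both = (pred > 0) & (ref > 0)
    if not both.any():
        raise ValueError("no jointly labeled pixels between map and reference")
    p = pred[both].astype(np.int64) - 1
    r = ref[both].astype(np.int64) - 1
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (p, r), 1)
    if legend is None:
        legend = {c: CLASS_NAMES[c] for c in range(1, n_classes + 1)}
    return ConfusionMatrix(counts=counts, legend=legend)


def producer_accuracy(cm: ConfusionMatrix, k) -> float:
    """100 · correct / reference-column total for class ``k`` (code or name).

    NaN when the class never occurs in the reference data.
    """
    i = _code_index(cm, k)
    col = cm.counts[:, i].sum()
    if col == 0:
        return float("nan")
    return 100.0 * cm.counts[i, i] / col


def user_accuracy(cm: ConfusionMatrix, k) -> float:
    """100 · correct / predicted-row total for class ``k``; NaN if never mapped."""
    i = _code_index(cm, k)
    row = cm.counts[i, :].sum()
    if row == 0:
        return float("nan")
    return 100.0 * cm.counts[i, i] / row


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """100 · trace / grand total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / cm.total
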