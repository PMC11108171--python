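"""Dice evaluation at whole-slide level and within annotated ROIs.

Conventions: two empty masks have Dice 1.0, one empty and one not 0.0;
the ROI summary reports median and inter-quartile range (Q3 - Q1 with
linear-interpolation quantiles).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Polygon

from .imgio import AnnotationSet, rasterize_polygons

__all__ = ["dice", "dice_in_roi", "dice_epithelium_within_tumor", "summarize"]


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b| / (|a|+|b|) of two aligned binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def summarize(values: Sequence[float]) -> dict:
    """Median and IQR (Q3 - Q1, linear interpolation) of Dice values."""
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"median": float(med), "iqr": float(q3 - q1), "q1": float(q1),
            "q3": float(q3), "n": len(v)}


def dice_in_roi(
    pred: np.ndarray,
    gt: np.ndarray,
    rois: AnnotationSet | Sequence[Polygon | MultiPolygon],
    downsample: float = 1.0,
) -> tuple[list[float], dict]:
    """Dice per ROI (masks clipped to the ROI first) plus median/IQR summary."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    if isinstance(rois, AnnotationSet):
        polys = [a.polygon for a in rois.select("roi") or rois]
    else:
        polys = list(rois)
    if not polys:
        raise ValueError("no ROIs given")
    values = []
    H, W = pred.shape
    for poly in polys:
        minx, miny, maxx, maxy = poly.bounds
        if maxx / downsample < 0 or maxy / downsample < 0 or (
            minx / downsample >= W or miny / downsample >= H
        ):
            raise ValueError("ROI lies outside the raster")
        roi = rasterize_polygons([poly], pred.shape, downsample)
        values.append(dice(pred & roi, gt & roi))
    return values, summarize(values)


def dice_epithelium_within_tumor(
    pred: np.ndarray, gt: np.ndarray, tumor_area: np.ndarray
) -> float:
    """Dice of two epithelium masks after clipping both to the tumor area."""
    t = np.asarray(tumor_area, dtype=bool)
    return dice(np.asarray(pred, dtype=bool) & t, np.asarray(gt, dtype=bool) & t)
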