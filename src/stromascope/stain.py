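"""Optical-density transform, color deconvolution, and conversion of a
DAB-stained cytokeratin IHC slide into a binary epithelium label mask.

Stains mix additively in optical-density space, so per-pixel stain
concentrations are recovered by solving the linear system defined by the
stain absorption vectors.  Defaults use base-10 OD and the standard
published H-DAB unit vectors; both are configurable because the source
protocol does not publish its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from .imgio import LabelMask, SlideImage, binary_mask

log = logging.getLogger(__name__)

# Ruifrok & Johnston H-DAB absorption vectors (rows: hematoxylin, DAB).
HEMATOXYLIN_RGB = (0.650, 0.704, 0.286)
DAB_RGB = (0.269, 0.568, 0.778)

__all__ = [
    "StainMatrix",
    "od_transform",
    "od_to_rgb",
    "deconvolve",
    "render_concentrations",
    "epithelium_mask_from_ihc",
]


@dataclass
class StainMatrix:
    """Three unit absorption vectors in OD-RGB space plus background I0.

    Rows are (hematoxylin, DAB, residual); the residual defaults to the
    normalized cross product of the first two so the basis is invertible.
    """

    matrix: np.ndarray = field(default=None)  # (3, 3)
    I0: float = 255.0

    def __post_init__(self) -> None:
        if self.matrix is None:
            h = np.asarray(HEMATOXYLIN_RGB, dtype=float)
            d = np.asarray(DAB_RGB, dtype=float)
            self.matrix = np.stack([h, d, np.cross(h, d)])
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(self.matrix, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain matrix has a zero row")
        self.matrix = self.matrix / norms[:, None]
        if np.linalg.cond(self.matrix) > 1e8:
            raise ValueError("stain matrix is singular or nearly so")
        self.inverse = np.linalg.inv(self.matrix)


def od_transform(rgb: np.ndarray, I0: float = 255.0) -> np.ndarray:
    """Per-channel optical density ``-log10(max(I, 1) / I0)``.

    Monotone decreasing in intensity and clipped to be non-negative.
    """
    if I0 <= 0:
        raise ValueError("I0 must be > 0")
    I = np.maximum(np.asarray(rgb, dtype=float), 1.0)
    return np.maximum(-np.log10(I / I0), 0.0)


def od_to_rgb(od: np.ndarray, I0: float = 255.0) -> np.ndarray:
    """Inverse of :func:`od_transform` (before uint8 quantization)."""
    return I0 * np.power(10.0, -np.asarray(od, dtype=float))


def deconvolve(od: np.ndarray, stains: StainMatrix) -> np.ndarray:
    """Unmix an OD image into per-stain concentrations.

    Solves ``od = c @ M`` per pixel via the matrix inverse; negative
    solutions (noise outside the stain simplex) are clamped to zero.
    Output has the same leading shape as ``od`` with 3 stain channels.
    """
    od = np.asarray(od, dtype=float)
    c = od @ stains.inverse
    return np.maximum(c, 0.0)


def render_concentrations(
    conc: np.ndarray, stains: StainMatrix, quantize: bool = True
) -> np.ndarray:
    """Synthesize an RGB image from per-stain concentrations.

    The forward model of :func:`deconvolve`: ``rgb = I0 * 10^-(c @ M)``.
    """
    od = np.asarray(conc, dtype=float) @ stains.matrix
    rgb = od_to_rgb(od, stains.I0)
    if quantize:
        return np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb


def epithelium_mask_from_ihc(
    ihc: SlideImage,
    tissue: LabelMask,
    stains: StainMatrix | None = None,
    threshold: str | float = "otsu",
    min_object_px: int = 50,
    level: int = 0,
) -> LabelMask:
    """Binary epithelium mask from the DAB channel of an IHC slide.

    The DAB concentration raster is thresholded (Otsu restricted to tissue
    pixels by default, or a fixed value), intersected with the tissue mask,
    and cleaned of objects smaller than ``min_object_px``.
    """
    stains = stains or StainMatrix()
    rgb = ihc.levels[level]
    if rgb.shape[:2] != tissue.data.shape:
        raise ValueError(
            f"ihc level {level} {rgb.shape[:2]} and tissue {tissue.data.shape} differ"
        )
    tissue_bool = tissue.data.astype(bool)
    if not tissue_bool.any():
        log.warning("empty tissue mask: returning all-zero epithelium mask")
        return binary_mask(np.zeros(tissue.data.shape, dtype=np.uint8), tissue.spacing_um)

    dab = deconvolve(od_transform(rgb, stains.I0), stains)[..., 1]
    vals = dab[tissue_bool]
    if threshold == "otsu":
        if np.ptp(vals) == 0:
            t = np.inf  # constant channel: nothing stands out
        else:
            t = threshold_otsu(vals)
    else:
        t = float(threshold)
    mask = (dab > t) & tissue_bool
    if min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    return binary_mask(mask, tissue.spacing_um)
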