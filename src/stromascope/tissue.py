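"""Classical tissue-background segmentation.

Bright-field background is near-white and unsaturated; tissue is colored.
Pixels are tissue when their HSV saturation exceeds an Otsu cut (computed
over non-near-white pixels only, which makes the mask invariant to white
padding) or their gray value falls below a darkness cut.  The raw mask is
closed morphologically and small holes are filled.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_holes

from .imgio import LabelMask, SlideImage, binary_mask

__all__ = ["tissue_mask"]


def tissue_mask(
    slide: SlideImage,
    level: int = 0,
    white_cut: float = 0.94,
    dark_cut: float = 0.80,
    close_radius_px: int = 2,
    min_hole_px: int = 64,
) -> LabelMask:
    """Binary tissue mask for one slide level.

    ``white_cut``/``dark_cut`` are gray-value fractions of full scale;
    pixels with gray >= white_cut never enter the Otsu statistic.
    """
    rgb = slide.levels[level]
    gray = rgb2gray(rgb)
    sat = rgb2hsv(rgb)[..., 1]

    candidates = gray < white_cut
    if not candidates.any():
        return binary_mask(np.zeros(gray.shape, dtype=np.uint8), slide.spacing_at(level))

    sat_vals = sat[candidates]
    if np.ptp(sat_vals) == 0:
        sat_cut = np.inf
    else:
        sat_cut = threshold_otsu(sat_vals)
    mask = candidates & ((sat > sat_cut) | (gray < dark_cut))

    if close_radius_px > 0:
        mask = closing(mask, disk(close_radius_px))
    if min_hole_px > 0:
        mask = remove_small_holes(mask, max_size=min_hole_px)
    return binary_mask(mask, slide.spacing_at(level))
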