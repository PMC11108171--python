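"""Tile sampling, augmentation, and patient-level cross-validation splits.

Tiles default to 512x512 px at 1.0 um/px; a tile is admissible when it
overlaps the tissue mask in at least ``tissue_floor`` of its pixels.
Splits are always by patient so no validation tile shares a patient with a
training tile.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize

from .imgio import LabelMask, SlideImage

__all__ = ["TileSample", "sample_tiles", "augment", "kfold_split"]


@dataclass
class TileSample:
    slide_id: str
    patient_id: str
    origin: tuple[int, int]  # (row, col) at the sampling spacing
    image: np.ndarray  # (size, size, 3) uint8
    label: np.ndarray  # (size, size) int
    fold: int | None = None

    def __post_init__(self) -> None:
        if self.image.shape[:2] != self.label.shape:
            raise ValueError("tile image and label rasters must share shape")


def _resample_to_spacing(
    rgb: np.ndarray, source_um: float, target_um: float, order: int
) -> np.ndarray:
    if abs(source_um - target_um) < 1e-9:
        return rgb
    scale = source_um / target_um
    shape = (max(int(round(rgb.shape[0] * scale)), 1), max(int(round(rgb.shape[1] * scale)), 1))
    out = resize(
        rgb.astype(float),
        shape + rgb.shape[2:],
        order=order,
        anti_aliasing=(order > 0 and scale < 1),
        preserve_range=True,
    )
    return np.round(out).astype(rgb.dtype) if order > 0 else out.astype(rgb.dtype)


def admissible_origins(
    tissue: np.ndarray, size: int, tissue_floor: float
) -> np.ndarray:
    """All (row, col) origins whose ``size``-square meets the tissue floor.

    Computed with a summed-area table; windows never extend past the raster
    (origins range over ``[0, dim - size]``).
    """
    t = np.asarray(tissue, dtype=np.int64)
    H, W = t.shape
    if H < size or W < size:
        return np.empty((0, 2), dtype=np.int64)
    sat = np.zeros((H + 1, W + 1), dtype=np.int64)
    sat[1:, 1:] = t.cumsum(0).cumsum(1)
    s = size
    win = sat[s:, s:] - sat[:-s, s:] - sat[s:, :-s] + sat[:-s, :-s]
    ok = win >= tissue_floor * s * s
    return np.argwhere(ok)


def sample_tiles(
    slide: SlideImage,
    labels: LabelMask,
    tissue: LabelMask,
    n: int,
    seed: int,
    size: int = 512,
    spacing_um: float = 1.0,
    tissue_floor: float = 0.2,
    slide_id: str = "",
    patient_id: str = "",
    level: int = 0,
) -> list[TileSample]:
    """Draw ``n`` tiles uniformly from admissible origins (with replacement).

    The slide, label, and tissue rasters are resampled to ``spacing_um``
    first (bilinear with anti-aliasing for the image, nearest for the label
    rasters).  Raises when no origin satisfies the tissue-fraction rule.
    """
    rgb = _resample_to_spacing(slide.levels[level], slide.spacing_at(level), spacing_um, 1)
    lab = _resample_to_spacing(labels.data, labels.spacing_um, spacing_um, 0)
    tis = _resample_to_spacing(
        tissue.data.astype(np.uint8), tissue.spacing_um, spacing_um, 0
    ).astype(bool)

    origins = admissible_origins(tis, size, tissue_floor)
    if len(origins) == 0:
        raise ValueError(f"slide {slide_id!r}: no admissible tile origin")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, len(origins), size=n)
    tiles = []
    for r, c in origins[picks]:
        tiles.append(
            TileSample(
                slide_id=slide_id,
                patient_id=patient_id,
                origin=(int(r), int(c)),
                image=rgb[r : r + size, c : c + size].copy(),
                label=lab[r : r + size, c : c + size].copy(),
            )
        )
    return tiles


def augment(
    tile: TileSample,
    seed: int,
    p: float = 0.5,
    blur_sigma: tuple[float, float] = (0.5, 1.5),
    hsv_shift: float = 0.05,
    contrast: float = 0.2,
    brightness: float = 0.2,
) -> TileSample:
    """Randomly flip, blur, and photometrically jitter a tile.

    Each transform fires independently with probability ``p``; flips are
    mirrored onto the label raster, photometric changes are not.  Decision
    draws happen in a fixed order (hflip, vflip, blur, hsv, contrast,
    brightness) so behaviour is reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    apply = rng.random(6) < p
    img = tile.image.astype(float)
    lab = tile.label.copy()

    if apply[0]:
        img = img[:, ::-1]
        lab = lab[:, ::-1]
    if apply[1]:
        img = img[::-1]
        lab = lab[::-1]
    if apply[2]:
        sigma = rng.uniform(*blur_sigma)
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    if apply[3]:
        hsv = rgb2hsv(np.clip(img, 0, 255).astype(np.uint8))
        shifts = rng.uniform(-hsv_shift, hsv_shift, size=3)
        hsv[..., 0] = (hsv[..., 0] + shifts[0]) % 1.0
        hsv[..., 1] = np.clip(hsv[..., 1] + shifts[1], 0, 1)
        hsv[..., 2] = np.clip(hsv[..., 2] + shifts[2], 0, 1)
        img = hsv2rgb(hsv) * 255.0
    if apply[4]:
        factor = 1.0 + rng.uniform(-contrast, contrast)
        img = (img - 127.5) * factor + 127.5
    if apply[5]:
        img = img + rng.uniform(-brightness, brightness) * 255.0

    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return replace(tile, image=np.ascontiguousarray(img), label=np.ascontiguousarray(lab))


def kfold_split(
    patient_ids: Sequence[str], k: int = 5, seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """Patient-level k-fold split: list of (train_ids, val_ids) per fold.

    Validation folds partition the patients with sizes differing by at most
    one.  Splitting is by patient — never by slide or tile — so tiles from
    one patient can never appear on both sides of a fold.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of patients ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    folds: list[list[str]] = [order[i::k] for i in range(k)]
    out = []
    for i in range(k):
        val = sorted(folds[i])
        train = sorted(x for j, f in enumerate(folds) if j != i for x in f)
        out.append((train, val))
    return out
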