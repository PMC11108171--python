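"""Stroma segmentation within the tumor bulk and tumor-stroma-ratio
computation across the entire bulk of a section.

The default ratio is ``stroma / (stroma + tumor epithelium)`` measured
inside the bulk, so high values mean stroma-rich tissue; other in-bulk
classes (lumen, necrosis stand-ins) are excluded from the denominator.  A
``denominator="bulk"`` variant divides by the whole bulk area instead.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .imgio import LabelMask, SlideImage, binary_mask
from .segnet import STROMA_CLASSES, SegModel, predict_wsi

__all__ = ["TSRReport", "segment_stroma", "compute_tsr"]


@dataclass
class TSRReport:
    slide_id: str
    area_tumor_epithelium_um2: float
    area_stroma_um2: float
    area_bulk_um2: float
    tsr: float
    alpha: float | None = None
    denominator: str = "stroma_plus_tumor"
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.tsr <= 1.0:
            raise ValueError(f"tsr {self.tsr} outside [0, 1]")
        if self.area_stroma_um2 + self.area_tumor_epithelium_um2 > self.area_bulk_um2 * (
            1 + 1e-9
        ):
            raise ValueError("component areas exceed bulk area")

    def to_row(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "tsr": self.tsr,
            "area_tumor_epithelium_um2": self.area_tumor_epithelium_um2,
            "area_stroma_um2": self.area_stroma_um2,
            "area_bulk_um2": self.area_bulk_um2,
            "alpha": self.alpha,
            "denominator": self.denominator,
        }


def _mask_hash(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def segment_stroma(
    slide: SlideImage,
    bulk: LabelMask,
    model: SegModel | list[SegModel] | LabelMask,
    window: int = 512,
    overlap: int = 128,
) -> LabelMask:
    """Stroma mask restricted to the tumor bulk.

    ``model`` is either trained stroma segmentation model(s) — the stand-in
    for a pre-trained multi-tissue network — or an oracle stroma LabelMask,
    in which case the truth is simply clipped to the bulk.
    """
    bulk_bool = bulk.data.astype(bool)
    if not bulk_bool.any():
        return binary_mask(np.zeros(bulk.data.shape, np.uint8), bulk.spacing_um)
    if isinstance(model, LabelMask):
        return binary_mask(model.data.astype(bool) & bulk_bool, bulk.spacing_um)
    _, labels = predict_wsi(
        model,
        slide,
        tissue=bulk,  # everything outside the bulk is forced to background
        window=window,
        overlap=overlap,
        spacing_um=bulk.spacing_um,
        class_codes=dict(STROMA_CLASSES),
    )
    stroma = labels.binary("stroma") & bulk_bool
    return binary_mask(stroma, bulk.spacing_um)


def compute_tsr(
    tumor_epi: LabelMask,
    stroma: LabelMask,
    bulk: LabelMask,
    spacing_um: float | None = None,
    slide_id: str = "",
    alpha: float | None = None,
    denominator: str = "stroma_plus_tumor",
) -> TSRReport:
    """Tumor-stroma ratio over the whole bulk of one section.

    Areas are reported in um^2 using the squared pixel spacing.  Where the
    two masks disagree (a pixel claimed as both stroma and tumor
    epithelium by independently trained models) the epithelium call wins,
    keeping the component areas disjoint.  A zero denominator (no stroma
    and no tumor epithelium inside the bulk) is an error: the ratio is
    undefined.
    """
    if denominator not in ("stroma_plus_tumor", "bulk"):
        raise ValueError(f"unknown denominator {denominator!r}")
    shapes = {tumor_epi.data.shape, stroma.data.shape, bulk.data.shape}
    if len(shapes) != 1:
        raise ValueError(f"misaligned masks: {shapes}")
    spacing_um = spacing_um or bulk.spacing_um

    b = bulk.data.astype(bool)
    if not b.any():
        raise ValueError("empty bulk mask")
    epi_b = tumor_epi.data.astype(bool) & b
    n_epi = int(epi_b.sum())
    n_str = int((stroma.data.astype(bool) & b & ~epi_b).sum())
    n_bulk = int(b.sum())
    if denominator == "stroma_plus_tumor":
        denom = n_str + n_epi
    else:
        denom = n_bulk
    if denom == 0:
        raise ValueError(f"slide {slide_id!r}: TSR undefined (empty denominator)")
    px = spacing_um**2
    return TSRReport(
        slide_id=slide_id,
        area_tumor_epithelium_um2=n_epi * px,
        area_stroma_um2=n_str * px,
        area_bulk_um2=n_bulk * px,
        tsr=n_str / denom,
        alpha=alpha,
        denominator=denominator,
        provenance={
            "tumor_epithelium": _mask_hash(tumor_epi.data),
            "stroma": _mask_hash(stroma.data),
            "bulk": _mask_hash(bulk.data),
        },
    )
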