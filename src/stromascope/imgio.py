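"""Raster, annotation and clinical-table I/O plus the coordinate conventions
shared by every other module.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``; windows are half-open
  ``[origin, origin + size)``.
* Polygon coordinates are ``(x, y) = (col, row)`` in level-0 pixels, the
  GeoJSON axis order.  The center of pixel ``(r, c)`` is the point
  ``(c, r)``; a pixel belongs to a polygon iff its center is inside or on
  the boundary.
* Physical scale is carried as micrometres per pixel (``spacing_um``) at
  level 0 and converted explicitly wherever resolutions are mixed.
* Out-of-bounds reads pad with white ``(255, 255, 255)`` — the background
  of a bright-field slide — never with zeros.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import MultiPolygon, Polygon

WHITE = 255

__all__ = [
    "SlideImage",
    "LabelMask",
    "Annotation",
    "AnnotationSet",
    "ClinicalRecord",
    "read_slide",
    "write_slide",
    "read_region",
    "polygons_to_mask",
    "rasterize_polygons",
    "read_annotations",
    "write_annotations",
    "read_mask",
    "write_mask",
    "read_clinical",
    "write_clinical",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SlideImage:
    """A multiresolution RGB raster with physical pixel spacing.

    ``levels[0]`` is the full-resolution raster; ``downsamples[i]`` is the
    integer (or near-integer) factor between level 0 and level ``i``.
    """

    levels: list[np.ndarray]
    spacing_um: float
    downsamples: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spacing_um <= 0:
            raise ValueError(f"spacing_um must be > 0, got {self.spacing_um}")
        if not self.downsamples:
            self.downsamples = [1.0] * len(self.levels)
        if len(self.downsamples) != len(self.levels):
            raise ValueError("one downsample factor per level required")
        prev = 0.0
        h0, w0 = self.levels[0].shape[:2]
        for i, (lv, ds) in enumerate(zip(self.levels, self.downsamples)):
            if ds < 1 or ds < prev:
                raise ValueError("downsamples must be >= 1 and non-decreasing")
            prev = ds
            h, w = lv.shape[:2]
            if abs(h - h0 // ds) > 1 or abs(w - w0 // ds) > 1:
                raise ValueError(
                    f"level {i} dims {(h, w)} inconsistent with downsample {ds}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def dimensions(self, level: int = 0) -> tuple[int, int]:
        """(height, width) of a pyramid level."""
        return self.levels[level].shape[:2]

    def spacing_at(self, level: int) -> float:
        return self.spacing_um * self.downsamples[level]


@dataclass
class LabelMask:
    """Integer raster aligned to a SlideImage level, with class semantics."""

    data: np.ndarray
    spacing_um: float
    class_codes: dict[int, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        present = set(np.unique(self.data).tolist())
        missing = present - set(self.class_codes)
        if missing:
            raise ValueError(f"pixel values {sorted(missing)} not in class-code table")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def binary(self, name: str) -> np.ndarray:
        """Boolean raster of the class with the given semantic name."""
        codes = [c for c, n in self.class_codes.items() if n == name]
        if not codes:
            raise KeyError(f"no class named {name!r}")
        return np.isin(self.data, codes)


BINARY_CODES = {0: "background", 1: "foreground"}


def binary_mask(data: np.ndarray, spacing_um: float) -> LabelMask:
    """Wrap a boolean/0-1 array as a binary LabelMask."""
    return LabelMask(np.asarray(data, dtype=np.uint8), spacing_um, dict(BINARY_CODES))


@dataclass
class Annotation:
    name: str
    role: str  # tumor_bulk | roi | other
    polygon: Polygon | MultiPolygon

    def __post_init__(self) -> None:
        geoms = (
            self.polygon.geoms
            if isinstance(self.polygon, MultiPolygon)
            else [self.polygon]
        )
        for g in geoms:
            if len(g.exterior.coords) < 4:  # closed ring: >= 3 distinct vertices
                raise ValueError(f"annotation {self.name!r}: ring with < 3 vertices")
            if g.area == 0:
                raise ValueError(f"annotation {self.name!r}: zero-area ring")


@dataclass
class AnnotationSet:
    """Named polygon collections in level-0 pixel coordinates (x=col, y=row)."""

    annotations: list[Annotation] = field(default_factory=list)

    def select(self, role: str | None = None) -> list[Annotation]:
        if role is None:
            return list(self.annotations)
        return [a for a in self.annotations if a.role == role]

    def __len__(self) -> int:
        return len(self.annotations)

    def __iter__(self):
        return iter(self.annotations)


@dataclass
class ClinicalRecord:
    """One patient's covariates and survival fields.

    ``survival_days`` is days-to-death when ``vital_status == "dead"`` and
    days-to-last-follow-up otherwise.
    """

    patient_id: str
    age: float
    gender: str
    vital_status: str  # "dead" | "alive"
    survival_days: int
    origin: str = "unknown"
    primary_diagnosis: str = "unknown"
    prior_malignancy: str = "unknown"
    slide_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vital_status not in ("dead", "alive"):
            raise ValueError(f"vital_status must be dead/alive, got {self.vital_status}")
        if self.survival_days < 0:
            raise ValueError(f"negative survival_days for {self.patient_id}")

    @property
    def event(self) -> bool:
        return self.vital_status == "dead"


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_slide(path: str | Path, spacing_um: float | None = None) -> SlideImage:
    """Read a pyramidal TIFF or a single-level PNG/TIFF as a SlideImage.

    Spacing resolution order: explicit ``spacing_um`` argument, then a JSON
    sidecar ``<path>.json`` with a ``spacing_um`` key.  Absent both, an
    error is raised demanding an explicit override.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if spacing_um is None:
        spacing_um = meta.get("spacing_um")
    if spacing_um is None:
        raise ValueError(
            f"{path}: no pixel spacing found; pass spacing_um explicitly or "
            "provide a JSON sidecar with a 'spacing_um' key"
        )

    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            levels = [np.asarray(lv.asarray()) for lv in series.levels]
    else:
        levels = [np.asarray(iio.imread(path))]

    levels = [_as_rgb(lv) for lv in levels]
    h0, w0 = levels[0].shape[:2]
    downs = [round(h0 / lv.shape[0], 6) for lv in levels]
    return SlideImage(levels=levels, spacing_um=float(spacing_um), downsamples=downs)


def _as_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr.astype(np.uint8, copy=False))


def write_slide(path: str | Path, slide: SlideImage) -> Path:
    """Write a SlideImage: pyramidal TIFF for multi-level, PNG otherwise.

    A JSON sidecar records the spacing either way so reads round-trip.
    """
    path = Path(path)
    if slide.n_levels > 1 or path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffWriter(path) as tw:
            opts = dict(tile=(256, 256), photometric="rgb")
            tw.write(slide.levels[0], subifds=slide.n_levels - 1, **opts)
            for lv in slide.levels[1:]:
                tw.write(lv, subfiletype=1, **opts)
    else:
        iio.imwrite(path, slide.levels[0])
    _sidecar(path).write_text(
        json.dumps({"spacing_um": slide.spacing_um, "downsamples": slide.downsamples})
    )
    return path


def read_region(
    slide: SlideImage,
    level: int,
    origin: tuple[int, int],
    size: tuple[int, int],
) -> np.ndarray:
    """Extract an RGB window ``[origin, origin+size)`` from a pyramid level.

    Area outside the raster is padded with white; the result always has
    shape ``(h, w, 3)``.
    """
    r0, c0 = origin
    h, w = size
    if h < 0 or w < 0:
        raise ValueError(f"negative window size {size}")
    lv = slide.levels[level]
    H, W = lv.shape[:2]
    out = np.full((h, w, 3), WHITE, dtype=np.uint8)
    rs, re = max(r0, 0), min(r0 + h, H)
    cs, ce = max(c0, 0), min(c0 + w, W)
    if rs < re and cs < ce:
        out[rs - r0 : re - r0, cs - c0 : ce - c0] = lv[rs:re, cs:ce]
    return out


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize_polygons(
    polygons: Iterable[Polygon | MultiPolygon],
    shape: tuple[int, int],
    downsample: float = 1.0,
) -> np.ndarray:
    """Rasterize level-0 polygons onto a grid of ``shape`` at ``downsample``.

    Pixel membership is decided by the pixel-center rule: the center of
    output pixel ``(r, c)`` sits at level-0 point ``(c * downsample,
    r * downsample)`` and counts as inside when it lies in the polygon or
    exactly on its boundary.
    """
    H, W = shape
    out = np.zeros((H, W), dtype=bool)
    for poly in polygons:
        geoms = poly.geoms if isinstance(poly, MultiPolygon) else [poly]
        for g in geoms:
            if g.is_empty:
                continue
            minx, miny, maxx, maxy = g.bounds
            c_lo = max(int(np.floor(minx / downsample)), 0)
            c_hi = min(int(np.ceil(maxx / downsample)) + 1, W)
            r_lo = max(int(np.floor(miny / downsample)), 0)
            r_hi = min(int(np.ceil(maxy / downsample)) + 1, H)
            if c_lo >= c_hi or r_lo >= r_hi:
                continue
            cc, rr = np.meshgrid(np.arange(c_lo, c_hi), np.arange(r_lo, r_hi))
            xs = cc.ravel() * downsample
            ys = rr.ravel() * downsample
            inside = shapely.intersects_xy(g, xs, ys)  # boundary counts IN
            out[rr.ravel()[inside], cc.ravel()[inside]] = True
    return out


def polygons_to_mask(
    ann: AnnotationSet,
    slide: SlideImage,
    level: int = 0,
    role: str | None = None,
) -> LabelMask:
    """Rasterize selected annotations onto a slide level as a binary mask.

    An empty selection yields an all-zero mask, not an error.
    """
    selected = ann.select(role)
    shape = slide.dimensions(level)
    mask = rasterize_polygons(
        [a.polygon for a in selected], shape, slide.downsamples[level]
    )
    return binary_mask(mask, slide.spacing_at(level))


# ---------------------------------------------------------------------------
# annotation I/O (GeoJSON)
# ---------------------------------------------------------------------------


def write_annotations(path: str | Path, ann: AnnotationSet) -> Path:
    path = Path(path)
    features = []
    for a in ann:
        geoms = (
            a.polygon.geoms if isinstance(a.polygon, MultiPolygon) else [a.polygon]
        )
        for g in geoms:
            ring = [list(xy) for xy in g.exterior.coords]
            if ring[0] != ring[-1]:
                ring.append(ring[0])  # explicit closure on write
            holes = []
            for interior in g.interiors:
                h = [list(xy) for xy in interior.coords]
                if h[0] != h[-1]:
                    h.append(h[0])
                holes.append(h)
            features.append(
                {
                    "type": "Feature",
                    "properties": {"name": a.name, "role": a.role},
                    "geometry": {"type": "Polygon", "coordinates": [ring, *holes]},
                }
            )
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
    return path


def read_annotations(path: str | Path) -> AnnotationSet:
    doc = json.loads(Path(path).read_text())
    anns = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        geom = feat["geometry"]
        if geom["type"] == "Polygon":
            polys = [geom["coordinates"]]
        elif geom["type"] == "MultiPolygon":
            polys = geom["coordinates"]
        else:
            raise ValueError(f"unsupported geometry type {geom['type']}")
        for rings in polys:
            poly = Polygon(rings[0], rings[1:])
            anns.append(
                Annotation(
                    name=props.get("name", "unnamed"),
                    role=props.get("role", "other"),
                    polygon=poly,
                )
            )
    return AnnotationSet(anns)


# ---------------------------------------------------------------------------
# mask I/O (single-channel PNG/TIFF + JSON sidecar)
# ---------------------------------------------------------------------------


def write_mask(path: str | Path, mask: LabelMask) -> Path:
    path = Path(path)
    iio.imwrite(path, mask.data.astype(np.uint8))
    _sidecar(path).write_text(
        json.dumps(
            {
                "spacing_um": mask.spacing_um,
                "class_codes": {str(k): v for k, v in mask.class_codes.items()},
            }
        )
    )
    return path


def read_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    data = np.asarray(iio.imread(path))
    if data.ndim == 3:
        data = data[..., 0]
    codes = {int(k): v for k, v in meta["class_codes"].items()}
    return LabelMask(data, float(meta["spacing_um"]), codes)


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_CATEGORICALS = ("gender", "origin", "primary_diagnosis", "prior_malignancy")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical CSV into records.

    Expected columns: ``patient_id, age, gender, vital_status,
    days_to_death, days_to_last_follow_up`` plus optional ``origin,
    primary_diagnosis, prior_malignancy, slide_ids`` (semicolon-joined).
    ``survival_days`` comes from days-to-death for the dead and
    days-to-last-follow-up for the living; unknown categoricals become the
    explicit level ``"unknown"``.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    dupes = df["patient_id"][df["patient_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate patient_id(s): {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        status = str(row["vital_status"]).strip().lower()
        days = row["days_to_death"] if status == "dead" else row["days_to_last_follow_up"]
        if pd.isna(days):
            raise ValueError(f"{row['patient_id']}: missing survival days field")
        if float(days) < 0:
            raise ValueError(f"{row['patient_id']}: negative survival days")
        cats = {
            k: (str(row[k]) if k in row and not pd.isna(row[k]) else "unknown")
            for k in _CATEGORICALS
        }
        slide_ids = []
        if "slide_ids" in row and not pd.isna(row["slide_ids"]):
            slide_ids = [s for s in str(row["slide_ids"]).split(";") if s]
        records.append(
            ClinicalRecord(
                patient_id=str(row["patient_id"]),
                age=float(row["age"]),
                vital_status=status,
                survival_days=int(round(float(days))),
                slide_ids=slide_ids,
                **cats,
            )
        )
    return records


def write_clinical(path: str | Path, records: Sequence[ClinicalRecord]) -> Path:
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "age": r.age,
                "gender": r.gender,
                "vital_status": r.vital_status,
                "days_to_death": r.survival_days if r.event else "",
                "days_to_last_follow_up": "" if r.event else r.survival_days,
                "origin": r.origin,
                "primary_diagnosis": r.primary_diagnosis,
                "prior_malignancy": r.prior_malignancy,
                "slide_ids": ";".join(r.slide_ids),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
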