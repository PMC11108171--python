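"""Synthetic paired pseudo-H&E / pseudo-IHC slide generation with exact
ground truth, plus synthetic survival cohorts.

A slide is a white canvas holding a tissue region; inside the tissue a
roughened circular tumor blob contains irregular thick-rimmed tumor glands,
while regular thin-rimmed normal glands lie outside the blob.  Stroma is
every tissue pixel that is neither epithelium nor gland lumen.  Gland
placement inside the blob is iterated until the stroma fraction

    stroma / (stroma + tumor epithelium)        (within the blob)

matches the recipe target to +/- 0.005, so downstream ratio accounting can
be verified against the recipe.  The pseudo-IHC image is synthesized
through the same stain model that downstream deconvolution inverts, making
the label-generation stage provably learnable.

Cohorts follow a proportional-hazards model with an exponential baseline:
patient hazard is ``baseline_rate * exp(beta * TSR)`` with independent
exponential censoring tuned to a requested censoring rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.optimize import brentq
from shapely.geometry import Polygon

from .imgio import (
    Annotation,
    AnnotationSet,
    ClinicalRecord,
    LabelMask,
    SlideImage,
    binary_mask,
    rasterize_polygons,
)
from .stain import StainMatrix, render_concentrations

__all__ = [
    "SlideRecipe",
    "CohortRecipe",
    "SlideTruth",
    "SynthesisError",
    "generate_slide",
    "generate_cohort",
]


class SynthesisError(RuntimeError):
    """Raised when a recipe cannot be realized within bounded retries."""


@dataclass
class GlandGeometry:
    outer_radius: float  # px, mean outer radius of the epithelial ring
    lumen_frac: float = 0.25  # lumen radius as fraction of outer radius
    radius_jitter: float = 0.08  # radial boundary noise amplitude
    eccentricity: float = 0.25  # max axis-ratio deviation from a circle


@dataclass
class SlideRecipe:
    canvas: tuple[int, int] = (512, 512)
    spacing_um: float = 1.0
    blob_center: tuple[float, float] | None = None  # (row, col); default canvas center
    blob_radius: float | None = None  # default 0.37 * min(canvas)
    blob_roughness: float = 0.12
    # normal glands: thin regular rings; tumor glands: thick irregular rims
    normal_gland: GlandGeometry = field(
        default_factory=lambda: GlandGeometry(
            outer_radius=11.0, lumen_frac=0.55, radius_jitter=0.06
        )
    )
    tumor_gland: GlandGeometry = field(
        default_factory=lambda: GlandGeometry(
            outer_radius=10.0, lumen_frac=0.30, radius_jitter=0.25, eccentricity=0.45
        )
    )
    n_normal_glands: int = 14
    target_stroma_fraction: float = 0.7
    tissue_margin_px: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_stroma_fraction <= 1.0:
            raise ValueError("target stroma fraction must lie in [0, 1]")
        for g in (self.normal_gland, self.tumor_gland):
            if g.outer_radius <= 0:
                raise ValueError("gland radii must be positive")
        H, W = self.canvas
        cr, cc = self.blob_center or (H / 2, W / 2)
        R = self.blob_radius or 0.37 * min(H, W)
        reach = R * (1 + self.blob_roughness) + 2
        if cr - reach < 0 or cc - reach < 0 or cr + reach > H or cc + reach > W:
            raise ValueError("tumor blob does not fit inside the canvas")

    @property
    def center(self) -> tuple[float, float]:
        H, W = self.canvas
        return self.blob_center or (H / 2, W / 2)

    @property
    def radius(self) -> float:
        return self.blob_radius or 0.37 * min(self.canvas)


@dataclass
class SlideTruth:
    """Exact ground truth accompanying a generated slide pair."""

    epithelium: LabelMask
    tumor_epithelium: LabelMask
    stroma: LabelMask
    tumor_bulk: AnnotationSet
    tissue: LabelMask
    blob: LabelMask  # rasterized tumor_bulk, for convenience
    lumen: LabelMask
    realized_stroma_fraction: float  # stroma/(stroma+tumor epi) within the blob


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _smooth_radial_noise(rng: np.random.Generator, n: int, amplitude: float) -> np.ndarray:
    """Periodic low-frequency radial perturbation in [-amplitude, amplitude]."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    noise = np.zeros(n)
    for k in range(2, 6):
        noise += rng.normal() * np.cos(k * theta) + rng.normal() * np.sin(k * theta)
    m = np.abs(noise).max()
    if m > 0:
        noise *= amplitude / m
    return noise


def _blob_polygon(rng: np.random.Generator, recipe: SlideRecipe) -> Polygon:
    cr, cc = recipe.center
    R = recipe.radius
    theta = np.linspace(0, 2 * np.pi, 96, endpoint=False)
    radii = R * (1 + _smooth_radial_noise(rng, 96, recipe.blob_roughness))
    xs = cc + radii * np.cos(theta)
    ys = cr + radii * np.sin(theta)
    return Polygon(np.stack([xs, ys], axis=1))


def _gland_stamp(
    rng: np.random.Generator, geom: GlandGeometry, scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Render one gland on a local grid: (epithelium ring, lumen disk)."""
    r_out = max(geom.outer_radius * scale, 3.0)
    r_lum = r_out * geom.lumen_frac
    ecc = 1.0 + rng.uniform(0, geom.eccentricity)
    phi = rng.uniform(0, np.pi)
    half = int(np.ceil(r_out * (1 + geom.radius_jitter) * ecc)) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    # rotate then squeeze one axis -> elliptical distance field
    xr = xx * np.cos(phi) + yy * np.sin(phi)
    yr = -xx * np.sin(phi) + yy * np.cos(phi)
    dist = np.hypot(xr / ecc, yr)
    ang = np.arctan2(yr, xr / ecc)
    # irregular boundary: radius modulated by low-frequency angular noise
    n_harm = 4
    mod = np.zeros_like(ang)
    for k in range(2, 2 + n_harm):
        mod += rng.normal() * np.cos(k * ang) + rng.normal() * np.sin(k * ang)
    m = np.abs(mod).max()
    if m > 0:
        mod *= geom.radius_jitter / m
    r_eff = r_out * (1 + mod)
    epi = (dist <= r_eff) & (dist > r_lum)
    lumen = dist <= r_lum
    return epi, lumen


def _paste(target: np.ndarray, stamp: np.ndarray, center: tuple[int, int]) -> None:
    """OR a boolean stamp into target centred at (row, col), clipped."""
    H, W = target.shape
    h, w = stamp.shape
    r0 = center[0] - h // 2
    c0 = center[1] - w // 2
    rs, re = max(r0, 0), min(r0 + h, H)
    cs, ce = max(c0, 0), min(c0 + w, W)
    if rs >= re or cs >= ce:
        return
    target[rs:re, cs:ce] |= stamp[rs - r0 : re - r0, cs - c0 : ce - c0]


# ---------------------------------------------------------------------------
# gland placement
# ---------------------------------------------------------------------------


def _fill_tumor_glands(
    rng: np.random.Generator,
    recipe: SlideRecipe,
    blob: np.ndarray,
    max_attempts: int = 30000,
) -> tuple[np.ndarray, np.ndarray]:
    """Place tumor glands inside the blob until the stroma fraction
    stroma/(stroma+epi) hits the target within +/-0.005."""
    target = recipe.target_stroma_fraction
    tol = 0.005
    H, W = blob.shape
    epi = np.zeros((H, W), dtype=bool)
    lumen = np.zeros((H, W), dtype=bool)
    B = int(blob.sum())
    if B == 0:
        raise SynthesisError("empty tumor blob")
    rows, cols = np.nonzero(blob)
    geom = recipe.tumor_gland
    nominal_area = np.pi * geom.outer_radius**2 * (1 - geom.lumen_frac**2)
    # the outermost glands define the bulk extent: seed a boundary band
    # first so a hull drawn around the glands recovers the blob
    edt = distance_transform_edt(blob)
    band = blob & (edt < 0.14 * np.sqrt(B / np.pi)) & (edt > 2)
    b_rows, b_cols = np.nonzero(band)
    n_seed = min(16, len(b_rows))

    def fraction() -> float:
        E = int(epi.sum())
        L = int((lumen & ~epi).sum())  # lumen overrun by later rims is epithelium
        denom = B - L
        return (B - E - L) / denom if denom > 0 else 0.0

    stall = 0
    n_placed = 0
    for attempt in range(max_attempts):
        f = fraction()
        if f <= target + tol:
            break
        if stall > 600:
            raise SynthesisError(
                f"target stroma fraction {target} infeasible for gland geometry "
                f"(stuck at {f:.3f} after {attempt} attempts)"
            )
        # remaining epithelium needed; shrink the last glands to land softly
        E, L = int(epi.sum()), int((lumen & ~epi).sum())
        needed = (1 - target) * (B - L) - E
        scale = float(np.clip(np.sqrt(max(needed, 1.0) / nominal_area), 0.25, 1.0))
        if n_placed < n_seed:
            i = rng.integers(len(b_rows))
            center = (int(b_rows[i]), int(b_cols[i]))
        else:
            i = rng.integers(len(rows))
            center = (int(rows[i]), int(cols[i]))
        g_epi, g_lum = _gland_stamp(rng, geom, scale)
        tmp_e = np.zeros((H, W), dtype=bool)
        tmp_l = np.zeros((H, W), dtype=bool)
        _paste(tmp_e, g_epi, center)
        _paste(tmp_l, g_lum, center)
        tmp_e &= blob  # tumor epithelium never leaves the bulk
        tmp_l &= blob
        new = int(tmp_e.sum())
        if new == 0:
            stall += 1
            continue
        overlap = int((tmp_e & (epi | lumen)).sum()) / new
        if overlap > 0.5:
            stall += 1
            continue
        stall = 0
        n_placed += 1
        epi |= tmp_e
        lumen |= tmp_l & ~epi
    else:
        raise SynthesisError(
            f"target stroma fraction {target} not reached within {max_attempts} attempts"
        )
    lumen &= ~epi
    return epi, lumen


def _place_normal_glands(
    rng: np.random.Generator,
    recipe: SlideRecipe,
    tissue: np.ndarray,
    blob: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Regular glands in the tissue outside (and clear of) the tumor blob."""
    H, W = tissue.shape
    allowed = tissue & ~blob
    epi = np.zeros((H, W), dtype=bool)
    lumen = np.zeros((H, W), dtype=bool)
    rows, cols = np.nonzero(allowed)
    if len(rows) == 0:
        return epi, lumen
    geom = recipe.normal_gland
    placed = 0
    for _ in range(recipe.n_normal_glands * 40):
        if placed >= recipe.n_normal_glands:
            break
        i = rng.integers(len(rows))
        center = (int(rows[i]), int(cols[i]))
        g_epi, g_lum = _gland_stamp(rng, geom)
        tmp_e = np.zeros((H, W), dtype=bool)
        tmp_l = np.zeros((H, W), dtype=bool)
        _paste(tmp_e, g_epi, center)
        _paste(tmp_l, g_lum, center)
        tmp_e &= allowed
        tmp_l &= allowed
        if tmp_e.sum() < 0.6 * g_epi.sum():  # clipped too much: near blob or border
            continue
        if (tmp_e & (epi | lumen)).any():
            continue
        epi |= tmp_e
        lumen |= tmp_l & ~epi
        placed += 1
    lumen &= ~epi
    return epi, lumen


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_STROMA_RGB = np.array([232.0, 176.0, 205.0])
_EPI_RGB = np.array([142.0, 84.0, 158.0])
_LUMEN_RGB = np.array([238.0, 233.0, 240.0])


def _render_he(
    rng: np.random.Generator,
    tissue: np.ndarray,
    epithelium: np.ndarray,
    lumen: np.ndarray,
) -> np.ndarray:
    H, W = tissue.shape
    img = np.full((H, W, 3), 251.0)
    stroma = tissue & ~epithelium & ~lumen
    # fibrous stroma: anisotropically smoothed noise modulating brightness
    fibres = gaussian_filter(rng.normal(size=(H, W)), sigma=(1.0, 5.0))
    fibres = 28.0 * fibres / (np.abs(fibres).max() + 1e-9)
    img[stroma] = _STROMA_RGB + fibres[stroma, None]
    img[lumen] = _LUMEN_RGB
    img[epithelium] = _EPI_RGB + rng.normal(scale=10.0, size=(int(epithelium.sum()), 3))
    img += rng.normal(scale=3.0, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _render_ihc(
    rng: np.random.Generator,
    tissue: np.ndarray,
    epithelium: np.ndarray,
    stains: StainMatrix,
) -> np.ndarray:
    H, W = tissue.shape
    conc = np.zeros((H, W, 3))
    # hematoxylin counterstain over all tissue, stronger in cellular areas
    conc[..., 0] = np.where(tissue, 0.35, 0.0) + np.where(epithelium, 0.25, 0.0)
    conc[..., 0] += np.where(tissue, np.abs(rng.normal(scale=0.05, size=(H, W))), 0.0)
    # DAB only where the epithelial marker binds
    dab = np.where(epithelium, 0.9, 0.0) + np.where(
        tissue, np.abs(rng.normal(scale=0.02, size=(H, W))), 0.0
    )
    conc[..., 1] = dab
    return render_concentrations(conc, stains)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def generate_slide(
    recipe: SlideRecipe, stains: StainMatrix | None = None
) -> tuple[SlideImage, SlideImage, SlideTruth]:
    """Generate a pixel-aligned pseudo-H&E / pseudo-IHC pair with truth.

    Deterministic in ``recipe.seed``; raises :class:`SynthesisError` when
    the target stroma fraction cannot be met with the gland geometry.
    """
    rng = np.random.default_rng(recipe.seed)
    stains = stains or StainMatrix()
    H, W = recipe.canvas
    sp = recipe.spacing_um

    m = recipe.tissue_margin_px
    tissue = np.zeros((H, W), dtype=bool)
    tissue[m : H - m, m : W - m] = True

    blob_poly = _blob_polygon(rng, recipe)
    blob = rasterize_polygons([blob_poly], (H, W)) & tissue

    tumor_epi, tumor_lumen = _fill_tumor_glands(rng, recipe, blob)
    normal_epi, normal_lumen = _place_normal_glands(rng, recipe, tissue, blob)
    epithelium = tumor_epi | normal_epi
    lumen = (tumor_lumen | normal_lumen) & ~epithelium
    stroma = tissue & ~epithelium & ~lumen

    he = SlideImage([_render_he(rng, tissue, epithelium, lumen)], spacing_um=sp)
    ihc = SlideImage([_render_ihc(rng, tissue, epithelium, stains)], spacing_um=sp)

    bulk_ann = AnnotationSet(
        [Annotation(name="tumor_bulk", role="tumor_bulk", polygon=blob_poly)]
    )
    E = int((tumor_epi & blob).sum())
    S = int((stroma & blob).sum())
    realized = S / (S + E) if S + E else 0.0
    truth = SlideTruth(
        epithelium=binary_mask(epithelium, sp),
        tumor_epithelium=binary_mask(tumor_epi, sp),
        stroma=binary_mask(stroma, sp),
        tumor_bulk=bulk_ann,
        tissue=binary_mask(tissue, sp),
        blob=binary_mask(blob, sp),
        lumen=binary_mask(lumen, sp),
        realized_stroma_fraction=realized,
    )
    return he, ihc, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortRecipe:
    n_patients: int = 100
    baseline_rate: float = 1.0 / 500.0  # events per day at TSR = 0
    beta: float = 3.0  # log-hazard per unit TSR
    censoring_rate: float = 0.3
    age_mean: float = 66.0
    age_sd: float = 9.0
    tsr_range: tuple[float, float] = (0.2, 0.95)
    slide_template: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.baseline_rate <= 0:
            raise ValueError("baseline rate must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring rate must lie in [0, 1)")


def _censoring_rate_for(lam_c: float, rates: np.ndarray) -> float:
    # P(censor before event) for independent exponentials
    return float(np.mean(lam_c / (lam_c + rates)))


def generate_cohort(
    recipe: CohortRecipe,
) -> tuple[list[ClinicalRecord], list[SlideRecipe]]:
    """Draw a synthetic cohort under proportional hazards.

    Each patient gets a true stroma ratio ``TSR ~ U(tsr_range)``, an event
    time ``Exp(baseline_rate * exp(beta * TSR))`` and an independent
    exponential censoring time tuned so the expected censored share equals
    ``censoring_rate``.  The patient's slide recipe reuses the TSR as its
    target stroma fraction.
    """
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_patients
    lo, hi = recipe.tsr_range
    tsr = rng.uniform(lo, hi, size=n)
    rates = recipe.baseline_rate * np.exp(recipe.beta * tsr)
    event_t = rng.exponential(1.0 / rates)

    if recipe.censoring_rate == 0:
        censor_t = np.full(n, np.inf)
    else:
        q = recipe.censoring_rate
        lam_c = brentq(
            lambda lam: _censoring_rate_for(lam, rates) - q,
            1e-12,
            1e6 * rates.max(),
        )
        censor_t = rng.exponential(1.0 / lam_c, size=n)

    observed = np.minimum(event_t, censor_t)
    dead = event_t <= censor_t
    ages = np.clip(rng.normal(recipe.age_mean, recipe.age_sd, size=n), 30, 95)
    genders = rng.choice(["female", "male"], size=n)

    records, slide_recipes = [], []
    for i in range(n):
        pid = f"P{i:04d}"
        sid = f"{pid}_S0"
        records.append(
            ClinicalRecord(
                patient_id=pid,
                age=round(float(ages[i]), 1),
                gender=str(genders[i]),
                vital_status="dead" if dead[i] else "alive",
                survival_days=int(np.ceil(observed[i])) if observed[i] > 0 else 0,
                origin="pancreas",
                primary_diagnosis="adenocarcinoma",
                prior_malignancy="no",
                slide_ids=[sid],
            )
        )
        slide_recipes.append(
            SlideRecipe(
                target_stroma_fraction=float(tsr[i]),
                seed=int(rng.integers(0, 2**31 - 1)),
                **recipe.slide_template,
            )
        )
    return records, slide_recipes
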