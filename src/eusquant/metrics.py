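"""Per-image gray-level quantities for pancreatic cystic lesions.

Everything is built on :class:`GrayMoments` — the exact integer triple
(pixel count, Σgray, Σgray²) of a region — from which the three reported
quantities follow:

* echogenicity  = mean gray value of the region (8-bit levels),
* inhomogeneity = standard deviation of the region's gray values,
* density       = Σgray divided by the region's calibrated area (Σgray·mm⁻²),
  algebraically ``mean × pixels_per_mm²``.

The solid part of a lesion is never delineated directly: its moments are the
whole-lesion moments minus the cystic-union moments, which is exactly
equivalent to measuring the set-difference mask.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .errors import (
    EmptyRegionError,
    FullyCysticError,
    InconsistentRegionsError,
    InputError,
    UndefinedSDError,
    ValidationError,
)
from .io import CalibratedImage, CalibrationSpec, LesionAnnotation, MEASUREMENT_COLUMNS
from .segmentation import (
    circle_inside_image,
    count_lobules,
    grow_region,
    pixel_count,
    rasterize_circle,
    rasterize_polygon,
    subtract_mask,
    union_masks,
)


@dataclasses.dataclass(frozen=True)
class GrayMoments:
    """Exact first and second gray-value moments of a pixel region."""

    n: int
    sum_gray: int
    sum_sq: int
    calibration: CalibrationSpec

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValidationError(f"pixel count must be >= 0, got {self.n}")
        if not (0 <= self.sum_gray <= 255 * self.n):
            raise ValidationError(f"sum_gray {self.sum_gray} outside [0, 255·n]")
        if not (0 <= self.sum_sq <= 255**2 * self.n):
            raise ValidationError(f"sum_sq {self.sum_sq} outside [0, 255²·n]")
        if self.sum_sq * self.n < self.sum_gray**2:
            raise ValidationError("moments violate the Cauchy–Schwarz inequality")

    @property
    def area_mm2(self) -> float:
        """Calibrated region area in mm²."""
        return self.n * self.calibration.pixel_area_mm2


def compute_moments(image: CalibratedImage, mask: np.ndarray) -> GrayMoments:
    """Accumulate (n, Σgray, Σgray²) over member pixels, in exact integers."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != image.gray.shape:
        raise InputError(f"mask shape {mask.shape} != image shape {image.gray.shape}")
    values = image.gray[mask].astype(np.int64)
    if values.size == 0:
        raise EmptyRegionError("cannot compute moments of an empty region")
    return GrayMoments(
        n=int(values.size),
        sum_gray=int(values.sum()),
        sum_sq=int((values**2).sum()),
        calibration=image.calibration,
    )


def mean_gray(m: GrayMoments) -> float:
    """Mean gray value of the region — its echogenicity."""
    if m.n < 1:
        raise EmptyRegionError("mean_gray undefined for an empty region")
    return m.sum_gray / m.n


def sd_gray(m: GrayMoments, sample: bool = True) -> float:
    """Standard deviation of the region's gray values — its inhomogeneity.

    ``sample=True`` (default) uses the n−1 denominator, matching mainstream
    image-measurement software; ``sample=False`` gives the population form.
    """
    if m.n < 2:
        raise UndefinedSDError("sd_gray requires at least 2 pixels")
    ss = m.sum_sq - m.sum_gray**2 / m.n
    ss = max(ss, 0.0)  # guard rounding at zero variance
    return math.sqrt(ss / (m.n - 1 if sample else m.n))


def density(m: GrayMoments) -> float:
    """Σgray divided by the region's calibrated area (Σgray · mm⁻²)."""
    if m.n < 1:
        raise EmptyRegionError("density undefined for an empty region")
    return m.sum_gray / (m.n * m.calibration.pixel_area_mm2)


def subtract_moments(whole: GrayMoments, cystic_union: GrayMoments) -> GrayMoments:
    """Moments of the solid part: whole-lesion moments minus cystic moments.

    Exactly equals computing moments on the set-difference mask, because the
    accumulators are plain sums over disjoint pixel sets.
    """
    if whole.calibration != cystic_union.calibration:
        raise InputError("whole and cystic moments carry different calibrations")
    n = whole.n - cystic_union.n
    s = whole.sum_gray - cystic_union.sum_gray
    ss = whole.sum_sq - cystic_union.sum_sq
    if n < 0 or s < 0 or ss < 0:
        raise InconsistentRegionsError(
            "cystic moments exceed whole-lesion moments; cystic part is not a subset"
        )
    if n == 0:
        raise FullyCysticError("cystic part covers the whole lesion; no solid part remains")
    try:
        return GrayMoments(n=n, sum_gray=s, sum_sq=ss, calibration=whole.calibration)
    except ValidationError as exc:
        raise InconsistentRegionsError(str(exc)) from exc


# ---------------------------------------------------------------------------
# per-image measurement record
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LesionMeasurement:
    """The per-image record: areas, echogenicity, inhomogeneity, density,
    area ratio and lobule count for the whole / cystic / solid lesion parts,
    plus the optional healthy-parenchyma reference. Missing parts (no cystic
    seeds, fully cystic lesion, no parenchyma block) are ``None``, never 0."""

    image_id: str
    group: Optional[str] = None
    patient_id: Optional[str] = None
    area_whole_mm2: float = math.nan
    area_cystic_mm2: Optional[float] = None
    area_solid_mm2: Optional[float] = None
    area_ratio: float = math.nan
    mean_whole: float = math.nan
    mean_cystic: Optional[float] = None
    mean_solid: Optional[float] = None
    sd_whole: float = math.nan
    sd_cystic: Optional[float] = None
    sd_solid: Optional[float] = None
    density_whole: float = math.nan
    density_cystic: Optional[float] = None
    density_solid: Optional[float] = None
    lobule_count: int = 0
    parenchyma_mean: Optional[float] = None
    parenchyma_sd: Optional[float] = None

    def to_row(self) -> dict:
        """Row dict in the fixed measurement-CSV column order."""
        return {col: getattr(self, col) for col in MEASUREMENT_COLUMNS}


@dataclasses.dataclass(frozen=True)
class ParenchymaResult:
    """Pooled statistics of the three 5-mm parenchyma reference circles."""

    mean: float
    sd: float
    n: int
    pair_pvalues: tuple[float, float, float]  # circles (0,1), (0,2), (1,2)
    pair_pass: tuple[bool, bool, bool]

    @property
    def homogeneous(self) -> bool:
        return all(self.pair_pass)


def measure_parenchyma(
    image: CalibratedImage,
    circles,
    calibration: Optional[CalibrationSpec] = None,
    alpha: float = 0.05,
    sample_sd: bool = True,
) -> ParenchymaResult:
    """Pooled mean/SD over the union of the three 5-mm reference discs, plus
    a homogeneity check: pairwise two-sample comparisons between the discs at
    level ``alpha`` (routed through the normality gate like every other
    two-sample comparison)."""
    from .stats import compare_two_samples  # local import: stats ↔ metrics layering

    circles = list(circles)
    if len(circles) != 3:
        raise ValidationError(f"exactly 3 parenchyma circles required, got {len(circles)}")
    calibration = calibration or image.calibration
    masks = []
    for i, circ in enumerate(circles):
        if not circle_inside_image(
            circ.center, circ.diameter_mm, calibration, image.width, image.height
        ):
            raise ValidationError(f"parenchyma_circles[{i}] at {circ.center} is not fully inside the image")
        masks.append(
            rasterize_circle(circ.center, circ.diameter_mm, calibration, image.width, image.height)
        )
    pooled = compute_moments(image, union_masks(masks))
    samples = [image.gray[m].astype(float) for m in masks]
    pvals = []
    verdicts = []
    for i, j in ((0, 1), (0, 2), (1, 2)):
        res = compare_two_samples(samples[i], samples[j], alpha=alpha)
        pvals.append(res.p_value)
        verdicts.append(not res.significant)
    return ParenchymaResult(
        mean=mean_gray(pooled),
        sd=sd_gray(pooled, sample=sample_sd),
        n=pooled.n,
        pair_pvalues=tuple(pvals),
        pair_pass=tuple(verdicts),
    )


def measure_lesion(
    image: CalibratedImage,
    annotation: LesionAnnotation,
    clip_to_lesion: bool = True,
    connectivity: int = 4,
    sample_sd: bool = True,
    group: Optional[str] = None,
    patient_id: Optional[str] = None,
    alpha: float = 0.05,
) -> LesionMeasurement:
    """Measure one annotated image.

    The whole-lesion mask is rasterized from the free-hand polygon; each
    cystic seed is grown with its tolerance (clipped to the lesion by
    default), the grown regions are merged by union before measurement so
    overlapping seeds are never double counted, and the solid part is the
    whole minus the cystic union by moment subtraction. A lesion whose
    cystic part covers it entirely gets missing solid metrics.
    """
    calib = annotation.calibration
    whole_mask = rasterize_polygon(annotation.lesion_polygon, image.width, image.height)
    if not whole_mask.any():
        raise ValidationError("lesion polygon rasterizes to an empty mask on this image")
    whole = compute_moments(image, whole_mask)

    rec = LesionMeasurement(image_id=annotation.image_id, group=group, patient_id=patient_id)
    rec.area_whole_mm2 = whole.n * calib.pixel_area_mm2
    rec.mean_whole = mean_gray(whole)
    rec.sd_whole = sd_gray(whole, sample=sample_sd)
    rec.density_whole = density(
        GrayMoments(whole.n, whole.sum_gray, whole.sum_sq, calibration=calib)
    )

    if annotation.cystic_seeds:
        grown = [
            grow_region(
                image,
                seed,
                constraint=whole_mask if clip_to_lesion else None,
                connectivity=connectivity,
            )
            for seed in annotation.cystic_seeds
        ]
        cystic_mask = union_masks(grown)
        if not clip_to_lesion:
            # unconstrained growth may leak outside the polygon; measurement is
            # always restricted to the lesion (subtract_mask reports strays)
            subtract_mask(whole_mask, cystic_mask)
            cystic_mask = whole_mask & cystic_mask
        cm = compute_moments(image, cystic_mask)
        cystic = GrayMoments(cm.n, cm.sum_gray, cm.sum_sq, calibration=calib)
        rec.area_cystic_mm2 = cystic.n * calib.pixel_area_mm2
        rec.mean_cystic = mean_gray(cystic)
        rec.sd_cystic = sd_gray(cystic, sample=sample_sd) if cystic.n >= 2 else None
        rec.density_cystic = density(cystic)
        rec.area_ratio = cystic.n / whole.n
        rec.lobule_count = count_lobules([cystic_mask], connectivity=connectivity)
        try:
            solid = subtract_moments(
                GrayMoments(whole.n, whole.sum_gray, whole.sum_sq, calibration=calib), cystic
            )
        except FullyCysticError:
            solid = None  # fully cystic: solid metrics stay missing
        if solid is not None:
            rec.area_solid_mm2 = solid.n * calib.pixel_area_mm2
            rec.mean_solid = mean_gray(solid)
            rec.sd_solid = sd_gray(solid, sample=sample_sd) if solid.n >= 2 else None
            rec.density_solid = density(solid)
    else:
        # no cystic seeds: solid part is the whole lesion
        rec.area_cystic_mm2 = None
        rec.area_ratio = 0.0
        rec.lobule_count = 0
        rec.area_solid_mm2 = rec.area_whole_mm2
        rec.mean_solid = rec.mean_whole
        rec.sd_solid = rec.sd_whole
        rec.density_solid = rec.density_whole

    if annotation.parenchyma_circles is not None:
        par = measure_parenchyma(
            image, annotation.parenchyma_circles, calib, alpha=alpha, sample_sd=sample_sd
        )
        rec.parenchyma_mean = par.mean
        rec.parenchyma_sd = par.sd
    return rec
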