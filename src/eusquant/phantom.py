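"""Seeded, ground-truthed synthetic B-mode phantoms and cohorts.

The generator emulates the *first-order* gray-level structure of
endoscopic-ultrasound stills of pancreatic cystic lesions: a bright
homogeneous parenchyma background, an elliptical lesion whose solid tissue
is darker than parenchyma, and one or more near-anechoic cystic lobules
inside it. Pixel noise is an independent truncated normal per region (the
measured quantities are all first-order statistics, so no spatially
correlated speckle model is required; a smoothing option exists for
qualitative realism). Every phantom carries a full truth record: per-region
masks, realized statistics, and the annotation a perfect annotator would
produce.

Group parameterizations mirror the printed per-group summary statistics of
the source cohort (echogenicity / inhomogeneity / area rows and the SEM-
derived between-image spreads); see ``default_group_specs``.
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .errors import InputError, ValidationError
from .io import (
    CalibratedImage,
    CalibrationSpec,
    LesionAnnotation,
    ParenchymaCircle,
    SeedSpec,
    write_annotation,
)
from .metrics import compute_moments, mean_gray, sd_gray
from .segmentation import write_mask_png


@dataclasses.dataclass(frozen=True)
class RegionNoise:
    """Truncated-normal pixel noise of one tissue region.

    ``mean`` is the *target realized* mean on the 8-bit scale: the generator
    inverts the [0, 255] truncation so the rendered region mean lands on it
    even when the lower tail would be cut (relevant for near-anechoic cysts).
    ``sd`` is the pre-truncation standard deviation.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (0 <= self.mean <= 255):
            raise ValidationError(f"region mean must be in [0, 255], got {self.mean}")
        if self.sd < 0:
            raise ValidationError(f"region sd must be >= 0, got {self.sd}")


@dataclasses.dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates with physical semi-axes."""

    center: tuple[float, float]  # (row, col) px
    semi_axes_mm: tuple[float, float]  # (row, col) mm

    def semi_axes_px(self, calibration: CalibrationSpec) -> tuple[float, float]:
        return (
            self.semi_axes_mm[0] * calibration.pixels_per_mm,
            self.semi_axes_mm[1] * calibration.pixels_per_mm,
        )

    def mask(self, calibration: CalibrationSpec, height: int, width: int) -> np.ndarray:
        ar, ac = self.semi_axes_px(calibration)
        rows = np.arange(height, dtype=float)[:, None]
        cols = np.arange(width, dtype=float)[None, :]
        return ((rows - self.center[0]) / ar) ** 2 + ((cols - self.center[1]) / ac) ** 2 <= 1.0


@dataclasses.dataclass(frozen=True)
class LobuleSpec:
    """One cystic lobule: its ellipse and its fluid-region noise."""

    ellipse: Ellipse
    noise: RegionNoise


@dataclasses.dataclass(frozen=True)
class WallSpec:
    """Optional hyperechoic wall band along the inside of the lesion boundary."""

    thickness_mm: float
    noise: RegionNoise


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic frame."""

    height: int = 960
    width: int = 1280
    calibration: CalibrationSpec = CalibrationSpec()
    background: RegionNoise = RegionNoise(68.3, 11.3)
    lesion: Optional[Ellipse] = None
    solid_noise: Optional[RegionNoise] = None
    lobules: tuple[LobuleSpec, ...] = ()
    wall: Optional[WallSpec] = None
    parenchyma_circles: Optional[tuple[tuple[float, float], ...]] = None  # explicit centers
    auto_parenchyma_circles: bool = True
    circle_diameter_mm: float = 5.0
    speckle_sigma_px: float = 0.0  # >0 smooths the continuous field before rounding
    seed: int = 0


@dataclasses.dataclass(frozen=True)
class RegionStats:
    """Realized (post-noise) statistics of one truth region."""

    n: int
    mean: float
    sd: float


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth of a rendered phantom.

    ``masks`` holds boolean membership maps per region name (``background``,
    ``whole``, ``cystic``, ``solid``, ``wall``, ``lobule_0`` …); ``realized``
    the exact post-noise statistics computed on those masks; ``annotation``
    the record a perfect annotator would produce (72-vertex boundary polygon,
    one representative seed per lobule with tolerance = half the solid–cystic
    mean gap, three parenchyma circles).
    """

    masks: dict[str, np.ndarray]
    realized: dict[str, RegionStats]
    annotation: Optional[LesionAnnotation]
    circles: Optional[tuple[ParenchymaCircle, ...]]


# ---------------------------------------------------------------------------
# noise sampling
# ---------------------------------------------------------------------------


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)


def _Phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2)))


def _truncnorm_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    """Closed-form mean of a normal truncated to [lo, hi]."""
    a, b = (lo - mu) / sd, (hi - mu) / sd
    z = _Phi(b) - _Phi(a)
    if z <= 0:  # numerically no mass inside: collapse to the nearer bound
        return lo if mu < lo else hi
    return mu + sd * (_phi(a) - _phi(b)) / z


def _invert_truncation(target_mean: float, sd: float, lo: float = 0.0, hi: float = 255.0) -> float:
    """Location μ of a normal whose [lo, hi]-truncation has the target mean."""
    if sd == 0:
        return target_mean

    def f(mu: float) -> float:
        return _truncnorm_mean(mu, sd, lo, hi) - target_mean

    span = 1.0
    low, high = target_mean - span * sd, target_mean + span * sd
    while f(low) > 0:
        span *= 2.0
        low = target_mean - span * sd
        if span > 64:
            raise InputError(f"cannot invert truncation for mean {target_mean}, sd {sd}")
    while f(high) < 0:
        span *= 2.0
        high = target_mean + span * sd
    return float(brentq(f, low, high, xtol=1e-10))


def _draw_region(rng: np.random.Generator, noise: RegionNoise, size: int) -> np.ndarray:
    """Continuous truncated-normal draws on [0, 255].

    Sampled by inverse CDF (exact truncated normal, efficient even when the
    truncation removes most of the mass, as it does for near-anechoic
    regions); deterministic given ``rng``.
    """
    if noise.sd == 0:
        return np.full(size, float(noise.mean))
    mu = _invert_truncation(noise.mean, noise.sd)
    a, b = (0.0 - mu) / noise.sd, (255.0 - mu) / noise.sd
    return truncnorm.rvs(a, b, loc=mu, scale=noise.sd, size=size, random_state=rng)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _ellipse_inside(outer: Ellipse, inner: Ellipse, calibration: CalibrationSpec, margin: float = 0.0) -> bool:
    """Boundary of ``inner`` within ``outer`` at normalized radius ≤ 1 − margin."""
    ar_o, ac_o = outer.semi_axes_px(calibration)
    ar_i, ac_i = inner.semi_axes_px(calibration)
    t = np.linspace(0, 2 * math.pi, 256, endpoint=False)
    br = inner.center[0] + ar_i * np.cos(t)
    bc = inner.center[1] + ac_i * np.sin(t)
    norm = ((br - outer.center[0]) / ar_o) ** 2 + ((bc - outer.center[1]) / ac_o) ** 2
    return bool(norm.max() <= (1.0 - margin) ** 2)


def _place_circles(
    spec: PhantomSpec, lesion_mask: Optional[np.ndarray]
) -> tuple[tuple[float, float], ...]:
    """Deterministically place three reference circles on free background.

    Scans a coarse grid top-left to bottom-right and keeps the first three
    centers whose discs stay inside the image, clear of the lesion (with a
    2-px margin) and of each other.
    """
    radius = 0.5 * spec.circle_diameter_mm * spec.calibration.pixels_per_mm
    margin = radius + 2.0
    step = max(4, int(radius / 2))
    clearance = None
    if lesion_mask is not None and lesion_mask.any():
        # distance from each pixel to the lesion; circle centers need >= margin
        clearance = ndimage.distance_transform_edt(~lesion_mask)
    chosen: list[tuple[float, float]] = []
    for r in range(int(math.ceil(margin)), int(spec.height - margin) + 1, step):
        for c in range(int(math.ceil(margin)), int(spec.width - margin) + 1, step):
            if clearance is not None and clearance[r, c] < margin:
                continue
            if any((r - pr) ** 2 + (c - pc) ** 2 < (2 * radius + 2) ** 2 for pr, pc in chosen):
                continue
            chosen.append((float(r), float(c)))
            if len(chosen) == 3:
                return tuple(chosen)
    raise ValidationError(
        "could not place three parenchyma circles on free background; "
        "image too small or lesion too large"
    )


def _pick_seed_pixel(
    gray: np.ndarray, lobule_mask: np.ndarray, center: tuple[float, float], target_mean: float
) -> tuple[int, int]:
    """Representative seed: the pixel near the lobule center whose gray value
    is closest to the lobule's realized mean (what a careful annotator picks)."""
    cr, cc = int(round(center[0])), int(round(center[1]))
    h, w = gray.shape
    for radius in (3, 6, 12):
        r0, r1 = max(0, cr - radius), min(h, cr + radius + 1)
        c0, c1 = max(0, cc - radius), min(w, cc + radius + 1)
        window = lobule_mask[r0:r1, c0:c1]
        if window.any():
            vals = np.where(window, np.abs(gray[r0:r1, c0:c1].astype(float) - target_mean), np.inf)
            idx = np.unravel_index(int(np.argmin(vals)), vals.shape)
            return (r0 + int(idx[0]), c0 + int(idx[1]))
    raise ValidationError(f"lobule around {center} rasterizes to an empty mask")


def render_phantom(spec: PhantomSpec) -> tuple[CalibratedImage, PhantomTruth]:
    """Render one phantom and its ground truth.

    Region priority where ellipses overlap: cyst > wall > solid > background.
    Identical ``spec`` (including ``seed``) gives a byte-identical image.
    """
    calib = spec.calibration
    h, w = spec.height, spec.width
    if spec.lesion is not None and spec.solid_noise is None:
        raise ValidationError("a lesion ellipse requires solid_noise")
    if spec.lesion is None and spec.lobules:
        raise ValidationError("lobules require a lesion ellipse")

    masks: dict[str, np.ndarray] = {}
    lesion_mask = None
    wall_mask = None
    lobule_masks: list[np.ndarray] = []
    if spec.lesion is not None:
        lesion_mask = spec.lesion.mask(calib, h, w)
        if not lesion_mask.any():
            raise ValidationError("lesion ellipse lies outside the image")
        if spec.wall is not None:
            ar, ac = spec.lesion.semi_axes_mm
            t = spec.wall.thickness_mm
            if t >= min(ar, ac):
                raise ValidationError("wall thickness exceeds the lesion semi-axes")
            inner = Ellipse(spec.lesion.center, (ar - t, ac - t))
            wall_mask = lesion_mask & ~inner.mask(calib, h, w)
        for i, lob in enumerate(spec.lobules):
            if not _ellipse_inside(spec.lesion, lob.ellipse, calib):
                raise ValidationError(f"lobule {i} is not inside the lesion ellipse")
            lobule_masks.append(lob.ellipse.mask(calib, h, w))

    # region labels with priority cyst > wall > solid > background
    region = np.zeros((h, w), dtype=np.int32)  # 0 background
    if lesion_mask is not None:
        region[lesion_mask] = 1  # solid
        if wall_mask is not None:
            region[wall_mask] = 2
        for i, m in enumerate(lobule_masks):
            region[m] = 3 + i

    rng = np.random.default_rng(spec.seed)
    field = np.empty((h, w), dtype=float)
    noises: list[tuple[int, RegionNoise]] = [(0, spec.background)]
    if lesion_mask is not None:
        noises.append((1, spec.solid_noise))
        if wall_mask is not None:
            noises.append((2, spec.wall.noise))
        for i, lob in enumerate(spec.lobules):
            noises.append((3 + i, lob.noise))
    for label, noise in noises:
        sel = region == label
        field[sel] = _draw_region(rng, noise, int(sel.sum()))
    if spec.speckle_sigma_px > 0:
        field = ndimage.gaussian_filter(field, spec.speckle_sigma_px)
    gray = np.floor(np.clip(field, 0.0, 255.0) + 0.5).astype(np.uint8)
    image = CalibratedImage(gray=gray, calibration=calib)

    # truth masks + realized statistics
    masks["background"] = region == 0
    realized: dict[str, RegionStats] = {}
    if lesion_mask is not None:
        cystic = np.zeros((h, w), dtype=bool)
        for m in lobule_masks:
            cystic |= m
        cystic &= lesion_mask
        masks["whole"] = lesion_mask
        masks["cystic"] = cystic
        masks["solid"] = lesion_mask & ~cystic
        if wall_mask is not None:
            masks["wall"] = wall_mask
        for i, m in enumerate(lobule_masks):
            masks[f"lobule_{i}"] = m
    for name, m in masks.items():
        if not m.any():
            continue
        mom = compute_moments(image, m)
        realized[name] = RegionStats(
            n=mom.n, mean=mean_gray(mom), sd=sd_gray(mom) if mom.n >= 2 else 0.0
        )

    # perfect-annotator record
    circles: Optional[tuple[ParenchymaCircle, ...]] = None
    centers = spec.parenchyma_circles
    if centers is None and spec.auto_parenchyma_circles:
        centers = _place_circles(spec, lesion_mask)
    if centers is not None:
        circles = tuple(ParenchymaCircle(c, spec.circle_diameter_mm) for c in centers)

    annotation = None
    if spec.lesion is not None:
        ar_px, ac_px = spec.lesion.semi_axes_px(calib)
        t = np.linspace(0, 2 * math.pi, 72, endpoint=False)
        polygon = np.column_stack(
            [spec.lesion.center[0] + ar_px * np.cos(t), spec.lesion.center[1] + ac_px * np.sin(t)]
        )
        seeds = []
        for i, lob in enumerate(spec.lobules):
            pos = _pick_seed_pixel(gray, lobule_masks[i], lob.ellipse.center, lob.noise.mean)
            tol = int(round(abs(spec.solid_noise.mean - lob.noise.mean) / 2.0))
            seeds.append(SeedSpec((float(pos[0]), float(pos[1])), min(255, max(0, tol))))
        annotation = LesionAnnotation(
            image_id=f"phantom_{spec.seed}",
            lesion_polygon=polygon,
            cystic_seeds=tuple(seeds),
            parenchyma_circles=circles,
            calibration=calib,
        )

    return image, PhantomTruth(masks=masks, realized=realized, annotation=annotation, circles=circles)


# ---------------------------------------------------------------------------
# group-level distributions and cohort generation
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GroupDistribution:
    """Distribution that per-image phantom specs are drawn from, for one
    diagnosis group. Between-image spreads are the printed per-group SEMs
    scaled by √n (the ± entries of the lesion rows read as standard errors);
    pixel-level spreads are the printed within-region inhomogeneity values.

    The per-image solid-tissue mean is *derived* from the drawn whole-lesion
    target mean and cystic mean through the mixture identity
    ``whole = f·cystic + (1−f)·solid`` — the printed summary rows are not
    mutually consistent, and the whole-lesion rows (the headline
    comparisons) are the ones preserved exactly.
    """

    name: str
    n_images: int
    n_patients: int
    area_mean_mm2: float
    area_between_sd_mm2: float
    cystic_fraction_mean: float
    cystic_fraction_sd: float
    lobule_count: int
    cystic_mean: float
    cystic_between_sd: float
    cystic_pixel_sd: float
    whole_mean: float
    whole_between_sd: float
    solid_pixel_sd: float
    parenchyma_mean: float
    parenchyma_pixel_sd: float
    height: int = 960
    width: int = 1280
    calibration: CalibrationSpec = CalibrationSpec()

    def draw_spec(
        self,
        rng: np.random.Generator,
        seed: int,
        area_scale: float = 1.0,
        shape: Optional[tuple[int, int]] = None,
        include_parenchyma: bool = True,
    ) -> PhantomSpec:
        """Draw one per-image phantom spec.

        ``area_scale`` scales lesion/lobule areas (not gray statistics) and
        ``shape`` overrides the frame size for scaled-down runs; both default
        to the study conditions.
        """
        h, w = shape if shape is not None else (self.height, self.width)
        calib = self.calibration
        # whole-lesion area, clipped to a plausible positive range
        area = float(
            np.clip(
                rng.normal(self.area_mean_mm2, self.area_between_sd_mm2),
                0.3 * self.area_mean_mm2,
                2.2 * self.area_mean_mm2,
            )
        ) * area_scale
        aspect = float(rng.uniform(0.6, 0.95))
        a_col = math.sqrt(area / (math.pi * aspect))  # mm, wide axis along columns
        a_row = aspect * a_col
        # keep the ellipse inside the frame with a small margin
        max_row = 0.42 * h / calib.pixels_per_mm
        max_col = 0.42 * w / calib.pixels_per_mm
        shrink = min(1.0, max_row / a_row, max_col / a_col)
        a_row, a_col = a_row * shrink, a_col * shrink
        center = (
            float(h / 2 + rng.uniform(-0.04, 0.04) * h),
            float(w / 2 + rng.uniform(-0.04, 0.04) * w),
        )
        lesion = Ellipse(center, (a_row, a_col))

        frac = float(
            np.clip(rng.normal(self.cystic_fraction_mean, self.cystic_fraction_sd), 0.08, 0.85)
        )
        cystic_mean = float(np.clip(rng.normal(self.cystic_mean, self.cystic_between_sd), 2.0, 100.0))
        whole_target = float(rng.normal(self.whole_mean, self.whole_between_sd))
        solid_mean = (whole_target - frac * cystic_mean) / (1.0 - frac)
        solid_mean = float(np.clip(solid_mean, cystic_mean + 2.0, 250.0))

        lobules = self._place_lobules(rng, lesion, frac, cystic_mean)
        return PhantomSpec(
            height=h,
            width=w,
            calibration=calib,
            background=RegionNoise(self.parenchyma_mean, self.parenchyma_pixel_sd),
            lesion=lesion,
            solid_noise=RegionNoise(solid_mean, self.solid_pixel_sd),
            lobules=lobules,
            auto_parenchyma_circles=include_parenchyma,
            seed=seed,
        )

    def _place_lobules(
        self,
        rng: np.random.Generator,
        lesion: Ellipse,
        frac: float,
        cystic_mean: float,
    ) -> tuple[LobuleSpec, ...]:
        """Slot non-overlapping lobule ellipses along one lesion axis.

        Placement happens in lesion-normalized coordinates (where the lesion
        is the unit disc and a lobule holding fraction fᵢ is an ellipse of
        normalized area fᵢ), which guarantees containment and disjointness
        in real space.
        """
        k = max(1, self.lobule_count)
        props = rng.dirichlet(np.full(k, 8.0)) if k > 1 else np.array([1.0])
        fracs = frac * props
        axis = int(rng.integers(0, 2))  # 0: slots along rows, 1: along columns
        span = 1.8
        widths = span * np.sqrt(fracs) / np.sqrt(fracs).sum()
        edges = -0.9 + np.concatenate([[0.0], np.cumsum(widths)])
        lobs = []
        ar, ac = lesion.semi_axes_mm
        for i in range(k):
            u = max(1e-3, widths[i] / 2 - 0.03)  # normalized semi-axis along the slot axis
            v = fracs[i] / u
            x = float(edges[i] + widths[i] / 2)  # slot center along the axis
            # cap the cross-axis semi-axis so the lobule stays in the unit disc
            u, v = _fit_in_unit_disc(x, u, v)
            ppm = self.calibration.pixels_per_mm
            if axis == 0:
                center = (lesion.center[0] + x * ar * ppm, lesion.center[1])
                semi = (u * ar, v * ac)
            else:
                center = (lesion.center[0], lesion.center[1] + x * ac * ppm)
                semi = (v * ar, u * ac)
            lobs.append(
                LobuleSpec(
                    ellipse=Ellipse(center, semi),
                    noise=RegionNoise(cystic_mean, self.cystic_pixel_sd),
                )
            )
        return tuple(lobs)


def _fit_in_unit_disc(x: float, u: float, v: float) -> tuple[float, float]:
    """Shrink a normalized lobule ellipse (center offset x along one axis,
    semi-axes u along it, v across) until it fits inside radius 0.97."""
    for _ in range(8):
        t = np.linspace(0, 2 * math.pi, 128, endpoint=False)
        norm = np.sqrt((x + u * np.cos(t)) ** 2 + (v * np.sin(t)) ** 2)
        m = float(norm.max())
        if m <= 0.97:
            return u, v
        scale = 0.97 / m
        u, v = u * scale, v * scale
    return u, v


def default_group_specs() -> dict[str, GroupDistribution]:
    """The three study-group parameterizations.

    Field-by-field provenance (all from the printed per-group summary table
    of the source cohort, ± read as SEM for lesion rows and as SD for the
    parenchyma row; between-image SD = SEM·√n):

    ==============  ==========  ==========  ==========
    field           SCN         Non-SCN     Pseudocyst
    ==============  ==========  ==========  ==========
    n images        30          81          59
    n patients      11          32          32
    whole area      415.8±64.2  433.2±47.4  590.4±77.6 mm²
    area ratio      57%         39%         61%
    lobules         2.1→2       2.4→2       1.2→1
    cystic gray     9.7±0.7     11.1±0.4    7.5±0.7
    whole gray      18.8±1.2    27.8±0.9    19.8±0.9
    cystic inhomog  7.1         6.9         7.1
    solid inhomog   16.1        21.1        24.3
    parenchyma      68.9±10.4   68.3±11.3   69.4±11.1 (SD)
    ==============  ==========  ==========  ==========
    """

    def sem_sd(sem: float, n: int) -> float:
        return sem * math.sqrt(n)

    return {
        "SCN": GroupDistribution(
            name="SCN",
            n_images=30,
            n_patients=11,
            area_mean_mm2=415.8,
            area_between_sd_mm2=sem_sd(64.2, 30),
            cystic_fraction_mean=0.57,
            cystic_fraction_sd=0.08,
            lobule_count=2,
            cystic_mean=9.7,
            cystic_between_sd=sem_sd(0.7, 30),
            cystic_pixel_sd=7.1,
            whole_mean=18.8,
            whole_between_sd=sem_sd(1.2, 30),
            solid_pixel_sd=16.1,
            parenchyma_mean=68.9,
            parenchyma_pixel_sd=10.4,
        ),
        "Non-SCN": GroupDistribution(
            name="Non-SCN",
            n_images=81,
            n_patients=32,
            area_mean_mm2=433.2,
            area_between_sd_mm2=sem_sd(47.4, 81),
            cystic_fraction_mean=0.39,
            cystic_fraction_sd=0.08,
            lobule_count=2,
            cystic_mean=11.1,
            cystic_between_sd=sem_sd(0.4, 81),
            cystic_pixel_sd=6.9,
            whole_mean=27.8,
            whole_between_sd=sem_sd(0.9, 81),
            solid_pixel_sd=21.1,
            parenchyma_mean=68.3,
            parenchyma_pixel_sd=11.3,
        ),
        "Pseudocyst": GroupDistribution(
            name="Pseudocyst",
            n_images=59,
            n_patients=32,
            area_mean_mm2=590.4,
            area_between_sd_mm2=sem_sd(77.6, 59),
            cystic_fraction_mean=0.61,
            cystic_fraction_sd=0.08,
            lobule_count=1,
            cystic_mean=7.5,
            cystic_between_sd=sem_sd(0.7, 59),
            cystic_pixel_sd=7.1,
            whole_mean=19.8,
            whole_between_sd=sem_sd(0.9, 59),
            solid_pixel_sd=24.3,
            parenchyma_mean=69.4,
            parenchyma_pixel_sd=11.1,
        ),
    }


def generate_cohort(
    out_dir,
    group_specs: Optional[dict[str, GroupDistribution]] = None,
    n_images: Optional[dict[str, int]] = None,
    master_seed: int = 0,
    area_scale: float = 1.0,
    shape: Optional[tuple[int, int]] = None,
    include_parenchyma: bool = True,
    save_truth: bool = False,
) -> pd.DataFrame:
    """Write a fully reproducible synthetic cohort to disk.

    Produces ``images/*.png``, ``annotations/*.json``, optional
    ``truth/*`` (realized-statistics JSON + mask PNGs), and
    ``manifest.csv`` with columns image_path, annotation_path, group,
    patient_id (paths relative to ``out_dir``). Identical arguments,
    including ``master_seed``, give byte-identical output.
    """
    import json

    group_specs = group_specs if group_specs is not None else default_group_specs()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    if save_truth:
        (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(master_seed)
    rows = []
    total = 0
    for group in group_specs:
        dist = group_specs[group]
        n = n_images[group] if n_images is not None else dist.n_images
        if n < 1:
            raise InputError(f"group {group!r}: at least one image required, got {n}")
        for i in range(n):
            child_seed = int(rng.integers(0, 2**31 - 1))
            spec = dist.draw_spec(
                rng,
                seed=child_seed,
                area_scale=area_scale,
                shape=shape,
                include_parenchyma=include_parenchyma,
            )
            image, truth = render_phantom(spec)
            image_id = f"{group.replace(' ', '_')}_{i:03d}"
            annotation = dataclasses.replace(truth.annotation, image_id=image_id)
            img_rel = f"images/{image_id}.png"
            ann_rel = f"annotations/{image_id}.json"
            from PIL import Image as _PILImage

            _PILImage.fromarray(image.gray, mode="L").save(out_dir / img_rel)
            write_annotation(annotation, out_dir / ann_rel)
            if save_truth:
                doc = {
                    name: dataclasses.asdict(stats) for name, stats in truth.realized.items()
                }
                with open(out_dir / "truth" / f"{image_id}.json", "w", encoding="utf-8") as fh:
                    json.dump(doc, fh, indent=1)
                for name in ("whole", "cystic", "solid"):
                    if name in truth.masks:
                        write_mask_png(
                            truth.masks[name], out_dir / "truth" / f"{image_id}_{name}.png"
                        )
            patient = f"{group.replace(' ', '_')}_pat{i % dist.n_patients:02d}"
            rows.append(
                {
                    "image_path": img_rel,
                    "annotation_path": ann_rel,
                    "group": group,
                    "patient_id": patient,
                }
            )
            total += 1
    if total == 0:
        raise InputError("cohort generation produced zero images")
    manifest = pd.DataFrame(rows, columns=["image_path", "annotation_path", "group", "patient_id"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
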