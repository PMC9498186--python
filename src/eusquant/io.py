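"""Image, annotation and measurement-table I/O with physical calibration.

Coordinate convention used throughout the package: pixel positions are
``(row, col)``, 0-based, with the pixel *center* at integer coordinates.
Polygon vertices, seed positions and circle centers are all expressed in
this frame.
"""
from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import ImageFormatError, InputError, ValidationError

#: Pixels-per-millimetre constant of the source ultrasound frames, taken from
#: the machine's on-screen distance scale.
DEFAULT_PIXELS_PER_MM = 12.2674

#: Fixed column order of the per-image measurement CSV.
MEASUREMENT_COLUMNS = [
    "image_id",
    "group",
    "area_whole_mm2",
    "area_cystic_mm2",
    "area_solid_mm2",
    "area_ratio",
    "mean_whole",
    "mean_cystic",
    "mean_solid",
    "sd_whole",
    "sd_cystic",
    "sd_solid",
    "density_whole",
    "density_cystic",
    "density_solid",
    "lobule_count",
    "parenchyma_mean",
    "parenchyma_sd",
]


@dataclasses.dataclass(frozen=True)
class CalibrationSpec:
    """Physical calibration of an ultrasound frame.

    Parameters
    ----------
    pixels_per_mm:
        Linear pixel density of the frame (pixels · mm⁻¹). Must be positive.

    The derived quantities ``pixels_per_mm2`` (pixel count per mm²) and
    ``pixel_area_mm2`` (physical area of one pixel) follow algebraically and
    are exposed as properties so the identity ``pixel_area_mm2 ==
    1 / pixels_per_mm**2`` holds exactly.
    """

    pixels_per_mm: float = DEFAULT_PIXELS_PER_MM

    def __post_init__(self) -> None:
        if not (self.pixels_per_mm > 0 and math.isfinite(self.pixels_per_mm)):
            raise ValidationError(
                f"pixels_per_mm must be a positive finite real, got {self.pixels_per_mm!r}"
            )

    @property
    def pixels_per_mm2(self) -> float:
        """Pixels per square millimetre."""
        return self.pixels_per_mm**2

    @property
    def pixel_area_mm2(self) -> float:
        """Physical area of a single pixel in mm²."""
        return 1.0 / self.pixels_per_mm**2


@dataclasses.dataclass(frozen=True)
class CalibratedImage:
    """An 8-bit grayscale pixel grid with physical calibration attached."""

    gray: np.ndarray
    calibration: CalibrationSpec

    def __post_init__(self) -> None:
        gray = np.asarray(self.gray)
        if gray.ndim != 2 or gray.shape[0] < 1 or gray.shape[1] < 1:
            raise ValidationError(f"gray must be a 2-D array, got shape {gray.shape}")
        if gray.dtype != np.uint8:
            if not np.issubdtype(gray.dtype, np.integer):
                raise ImageFormatError(f"gray values must be integers, got dtype {gray.dtype}")
            if gray.min() < 0 or gray.max() > 255:
                raise ImageFormatError("gray values outside the 8-bit range [0, 255]")
            gray = gray.astype(np.uint8)
        object.__setattr__(self, "gray", gray)

    @property
    def height(self) -> int:
        return self.gray.shape[0]

    @property
    def width(self) -> int:
        return self.gray.shape[1]


@dataclasses.dataclass(frozen=True)
class SeedSpec:
    """A seed pixel for tolerance-based region growing.

    ``tolerance`` is the maximum permitted absolute gray-value difference
    between the seed pixel and any pixel included in the grown region.
    """

    position: tuple[float, float]  # (row, col)
    tolerance: int

    def __post_init__(self) -> None:
        if not (isinstance(self.tolerance, (int, np.integer)) and 0 <= self.tolerance <= 255):
            raise ValidationError(
                f"seed tolerance must be an integer in [0, 255], got {self.tolerance!r}"
            )


@dataclasses.dataclass(frozen=True)
class ParenchymaCircle:
    """A circular reference ROI on healthy pancreatic parenchyma."""

    center: tuple[float, float]  # (row, col)
    diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if not (self.diameter_mm > 0):
            raise ValidationError(
                f"parenchyma circle diameter must be positive, got {self.diameter_mm!r}"
            )


def point_in_polygon(point: Sequence[float], polygon: np.ndarray) -> bool:
    """Even-odd point-in-polygon test with the half-open top-left rule.

    A point exactly on a left/top boundary counts as inside, on a
    right/bottom boundary as outside — the same convention used by
    :func:`eusquant.segmentation.rasterize_polygon`, so seed-in-polygon
    validation and rasterized membership never disagree.
    """
    verts = np.asarray(polygon, dtype=float)
    pr, pc = float(point[0]), float(point[1])
    inside = False
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if (r1 > pr) != (r2 > pr):
            c_int = c1 + (pr - r1) * (c2 - c1) / (r2 - r1)
            if pc < c_int:
                inside = not inside
    return inside


@dataclasses.dataclass(frozen=True)
class LesionAnnotation:
    """Persisted form of the interactive selections made on one image.

    Holds the free-hand lesion outline (as a polygon), the cystic seed
    points with their tracing-tool tolerances, the optional trio of 5-mm
    healthy-parenchyma reference circles, and the frame calibration.
    """

    image_id: str
    lesion_polygon: np.ndarray  # (n, 2) float array of (row, col)
    cystic_seeds: tuple[SeedSpec, ...] = ()
    parenchyma_circles: Optional[tuple[ParenchymaCircle, ...]] = None
    calibration: CalibrationSpec = CalibrationSpec()

    def __post_init__(self) -> None:
        poly = np.asarray(self.lesion_polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValidationError(
                f"lesion_polygon needs >= 3 (row, col) vertices, got shape {poly.shape}"
            )
        shp = _ShapelyPolygon(poly)
        if not shp.is_valid:
            raise ValidationError("lesion_polygon must be a simple (non-self-intersecting) polygon")
        if shp.area <= 0:
            raise ValidationError("lesion_polygon is degenerate (zero area)")
        object.__setattr__(self, "lesion_polygon", poly)
        object.__setattr__(self, "cystic_seeds", tuple(self.cystic_seeds))
        for i, seed in enumerate(self.cystic_seeds):
            if not point_in_polygon(seed.position, poly):
                raise ValidationError(
                    f"cystic_seeds[{i}] at {seed.position} lies outside lesion_polygon"
                )
        if self.parenchyma_circles is not None:
            circles = tuple(self.parenchyma_circles)
            if len(circles) != 3:
                raise ValidationError(
                    f"parenchyma_circles requires exactly 3 circles when present, got {len(circles)}"
                )
            object.__setattr__(self, "parenchyma_circles", circles)


# ---------------------------------------------------------------------------
# image loading
# ---------------------------------------------------------------------------

# BT.601 luma weights for collapsing color frames to 8-bit luminance.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def load_grayscale_image(path, calibration: CalibrationSpec = CalibrationSpec()) -> CalibratedImage:
    """Load a PNG/JPEG still frame as a calibrated 8-bit grayscale image.

    Color inputs are collapsed to luminance with BT.601 weights
    (0.299, 0.587, 0.114) and rounded half-up; images deeper than 8 bits
    per channel are rejected.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode in ("P", "PA"):
                im = im.convert("RGBA" if mode == "PA" else "RGB")
                mode = im.mode
            arr = np.asarray(im)
    except UnidentifiedImageError as exc:
        raise InputError(f"cannot decode image file: {path}") from exc
    if arr.ndim == 2:
        if arr.dtype == np.uint8:
            gray = arr
        elif arr.dtype == bool:
            gray = arr.astype(np.uint8) * 255
        else:
            raise ImageFormatError(
                f"{path}: bit depth deeper than 8 bits per pixel is unsupported (dtype {arr.dtype})"
            )
    elif arr.ndim == 3:
        if arr.dtype != np.uint8:
            raise ImageFormatError(
                f"{path}: bit depth deeper than 8 bits per channel is unsupported"
            )
        rgb = arr[..., :3].astype(np.float64)
        luma = rgb @ _LUMA_WEIGHTS
        gray = np.floor(luma + 0.5).astype(np.uint8)  # round half-up
    else:
        raise ImageFormatError(f"{path}: unsupported image layout with shape {arr.shape}")
    return CalibratedImage(gray=gray, calibration=calibration)


# ---------------------------------------------------------------------------
# annotation files
# ---------------------------------------------------------------------------


def read_annotation(path) -> LesionAnnotation:
    """Read and validate a JSON annotation file.

    Schema (documented in the README): ``image_id``, ``pixels_per_mm``,
    ``lesion_polygon`` = list of ``[row, col]``, ``cystic_seeds`` = list of
    ``{"row", "col", "tolerance"}``, optional ``parenchyma_circles`` = list
    of ``{"row", "col", "diameter_mm"}``.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"annotation not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InputError(f"annotation is not valid JSON: {path}: {exc}") from exc
    try:
        image_id = str(doc["image_id"])
        polygon = doc["lesion_polygon"]
    except KeyError as exc:
        raise ValidationError(f"{path}: missing required field {exc.args[0]!r}") from exc
    calibration = CalibrationSpec(float(doc.get("pixels_per_mm", DEFAULT_PIXELS_PER_MM)))
    seeds = []
    for i, entry in enumerate(doc.get("cystic_seeds", [])):
        try:
            tol = entry["tolerance"]
            if isinstance(tol, float) and not tol.is_integer():
                raise ValidationError(
                    f"cystic_seeds[{i}].tolerance must be an integer, got {tol!r}"
                )
            seeds.append(SeedSpec((float(entry["row"]), float(entry["col"])), int(tol)))
        except KeyError as exc:
            raise ValidationError(f"cystic_seeds[{i}]: missing field {exc.args[0]!r}") from exc
    circles_doc = doc.get("parenchyma_circles")
    circles = None
    if circles_doc is not None:
        circles = tuple(
            ParenchymaCircle(
                (float(c["row"]), float(c["col"])), float(c.get("diameter_mm", 5.0))
            )
            for c in circles_doc
        )
    return LesionAnnotation(
        image_id=image_id,
        lesion_polygon=np.asarray(polygon, dtype=float),
        cystic_seeds=tuple(seeds),
        parenchyma_circles=circles,
        calibration=calibration,
    )


def write_annotation(annotation: LesionAnnotation, path) -> None:
    """Serialize a :class:`LesionAnnotation` back to the JSON schema."""
    doc = {
        "image_id": annotation.image_id,
        "pixels_per_mm": annotation.calibration.pixels_per_mm,
        "lesion_polygon": [[float(r), float(c)] for r, c in annotation.lesion_polygon],
        "cystic_seeds": [
            {"row": s.position[0], "col": s.position[1], "tolerance": s.tolerance}
            for s in annotation.cystic_seeds
        ],
    }
    if annotation.parenchyma_circles is not None:
        doc["parenchyma_circles"] = [
            {"row": c.center[0], "col": c.center[1], "diameter_mm": c.diameter_mm}
            for c in annotation.parenchyma_circles
        ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------


def write_measurements(records, path) -> None:
    """Write per-image measurement records to CSV (one row per image).

    ``records`` is a non-empty sequence of
    :class:`eusquant.metrics.LesionMeasurement`. Missing metrics (no solid
    part, no parenchyma block) become empty cells, never zeros. Values
    survive a write/read round trip to at least 6 significant digits.
    """
    records = list(records)
    if not records:
        raise InputError("write_measurements requires a non-empty record list")
    rows = [rec.to_row() for rec in records]
    frame = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def read_measurements(path) -> pd.DataFrame:
    """Read a measurement CSV back into a DataFrame (missing cells → NaN)."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"measurement table not found: {path}")
    frame = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing measurement columns {missing}")
    return frame
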