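"""Pixel-mask construction: polygon rasterization, tolerance-based seeded
region growing, circular ROIs, mask algebra and lobule counting.

Masks are plain 2-D boolean numpy arrays in the package-wide ``(row, col)``
pixel-center coordinate frame. All operations are deterministic.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon

from .errors import InputError, ValidationError
from .io import CalibratedImage, CalibrationSpec, SeedSpec

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCTURE_4
    if connectivity == 8:
        return _STRUCTURE_8
    raise InputError(f"connectivity must be 4 or 8, got {connectivity!r}")


def rasterize_polygon(polygon, width: int, height: int) -> np.ndarray:
    """Rasterize a simple polygon onto a ``height × width`` pixel grid.

    A pixel is a member iff its center lies inside the polygon under the
    even-odd rule; centers exactly on an edge are resolved by the half-open
    top-left rule (left/top boundaries inside, right/bottom outside), which
    makes adjacent polygons tile without overlap and is independent of
    vertex orientation. The mask is clipped to the image bounds.
    """
    verts = np.asarray(polygon, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise ValidationError(f"polygon needs >= 3 (row, col) vertices, got shape {verts.shape}")
    shp = _ShapelyPolygon(verts)
    if not shp.is_valid:
        raise ValidationError("polygon must be simple (non-self-intersecting)")
    if shp.area <= 0:
        raise ValidationError("polygon is degenerate (zero area)")
    # Scanline even-odd fill: for each edge crossing a pixel row, toggle the
    # parity of every pixel whose center column is strictly left of the
    # crossing. Prefix toggles are accumulated in a difference array.
    diff = np.zeros((height, width + 1), dtype=np.int64)
    rows = np.arange(height, dtype=float)
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        if r1 == r2:
            continue  # horizontal edges never satisfy the half-open row test
        crossing = (r1 > rows) != (r2 > rows)
        if not crossing.any():
            continue
        rr = rows[crossing]
        c_int = c1 + (rr - r1) * (c2 - c1) / (r2 - r1)
        k = np.clip(np.ceil(c_int), 0, width).astype(np.int64)
        idx = np.nonzero(crossing)[0]
        np.add.at(diff, (idx, np.zeros_like(k)), 1)
        np.add.at(diff, (idx, k), -1)
    counts = np.cumsum(diff, axis=1)[:, :width]
    return (counts % 2).astype(bool)


def grow_region(
    image: CalibratedImage,
    seed: SeedSpec,
    constraint: np.ndarray | None = None,
    connectivity: int = 4,
) -> np.ndarray:
    """Tolerance-based seeded region growing (the tracing-tool operation).

    Returns the maximal connected component containing the seed of the set
    ``{p : |gray(p) − gray(seed)| ≤ tolerance}``, intersected with
    ``constraint`` when given. The admissible band is anchored to the seed
    pixel's gray value, so the result is independent of any visit order.
    """
    r, c = seed.position
    ri, ci = int(round(r)), int(round(c))
    if not (0 <= ri < image.height and 0 <= ci < image.width):
        raise InputError(f"seed {seed.position} out of image bounds {image.gray.shape}")
    if constraint is not None:
        constraint = np.asarray(constraint, dtype=bool)
        if constraint.shape != image.gray.shape:
            raise InputError(
                f"constraint shape {constraint.shape} != image shape {image.gray.shape}"
            )
        if not constraint[ri, ci]:
            raise InputError(f"seed {seed.position} is outside the constraint mask")
    seed_gray = int(image.gray[ri, ci])
    band = np.abs(image.gray.astype(np.int16) - seed_gray) <= seed.tolerance
    if constraint is not None:
        band &= constraint
    labels, _ = ndimage.label(band, structure=_structure(connectivity))
    return labels == labels[ri, ci]


def rasterize_circle(
    center,
    diameter_mm: float,
    calibration: CalibrationSpec,
    width: int,
    height: int,
) -> np.ndarray:
    """Rasterize a physically-sized disc: members are pixel centers within
    ``diameter_mm/2 · pixels_per_mm`` (Euclidean) of ``center``, clipped to
    the image. A circle with no member pixel inside the image is rejected.
    """
    if not diameter_mm > 0:
        raise ValidationError(f"diameter_mm must be positive, got {diameter_mm!r}")
    cr, cc = float(center[0]), float(center[1])
    radius_px = 0.5 * diameter_mm * calibration.pixels_per_mm
    rows = np.arange(height, dtype=float)[:, None]
    cols = np.arange(width, dtype=float)[None, :]
    mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= radius_px**2
    if not mask.any():
        raise ValidationError(
            f"circle at {center} (diameter {diameter_mm} mm) lies fully outside the image"
        )
    return mask


def circle_inside_image(center, diameter_mm, calibration, width, height) -> bool:
    """True when the disc is entirely inside the image bounds."""
    radius_px = 0.5 * diameter_mm * calibration.pixels_per_mm
    cr, cc = float(center[0]), float(center[1])
    return (
        cr - radius_px >= -0.5
        and cc - radius_px >= -0.5
        and cr + radius_px <= height - 0.5
        and cc + radius_px <= width - 0.5
    )


def union_masks(masks) -> np.ndarray:
    """Pixelwise logical OR of one or more same-shaped masks."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise InputError("union_masks requires at least one mask")
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise InputError(f"mask dimension mismatch: {m.shape} != {shape}")
    out = masks[0].copy()
    for m in masks[1:]:
        out |= m
    return out


def subtract_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference ``a \\ b``. ``b`` is expected to be a subset of ``a``;
    stray ``b`` pixels outside ``a`` are discarded with a warning that
    reports their count (annotation-noise tolerance)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise InputError(f"mask dimension mismatch: {a.shape} != {b.shape}")
    stray = int(np.count_nonzero(b & ~a))
    if stray:
        warnings.warn(
            f"subtract_mask: {stray} pixels of the subtrahend lie outside the parent "
            "mask and were discarded",
            stacklevel=2,
        )
    return a & ~b


def count_lobules(cystic_masks, connectivity: int = 4) -> int:
    """Number of connected components of the union of cystic masks.

    Two seeds that grew into touching regions count as one lobule; an empty
    list means zero lobules.
    """
    cystic_masks = list(cystic_masks)
    if not cystic_masks:
        return 0
    merged = union_masks(cystic_masks)
    _, n = ndimage.label(merged, structure=_structure(connectivity))
    return int(n)


def pixel_count(mask: np.ndarray) -> int:
    """Number of member pixels of a mask."""
    return int(np.count_nonzero(mask))


def write_mask_png(mask: np.ndarray, path) -> None:
    """Export a mask as an 8-bit 0/255 PNG for audit."""
    from PIL import Image

    Image.fromarray(np.asarray(mask, dtype=bool).astype(np.uint8) * 255, mode="L").save(path)
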