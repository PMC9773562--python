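"""ImageJ-compatible seed/pod shape morphometrics.

Implements the image half of the phenomic characterization protocol:
histogram thresholding (Kapur maximum-entropy and Huang fuzzy methods),
connected-component ROI extraction, and extraction of the twelve particle
shape descriptors (area, perimeter, width, height, major, minor, Feret,
MinFeret, aspect ratio, circularity, roundness, solidity) in calibrated
units, following ImageJ particle-analysis conventions.

Conventions
-----------
* Images are 2-D arrays with intensities in [0, 255]; RGB input is reduced
  to luminance 0.299 R + 0.587 G + 0.114 B.
* Coordinates are row-major, origin top-left, 0-based.
* Foreground connectivity is 8-connected (ImageJ particle-analysis default).
* Feret diameters use pixel-center coordinates: the maximum Feret is the
  largest distance between convex-hull pixel centers, the minimum Feret is
  the smallest projection width of hull pixel centers over a 0.1 degree
  caliper sweep.
* The perimeter is a Crofton 4-direction boundary crack-count estimate, so
  a rasterized disk has circularity ~= 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as _skmeasure

__all__ = [
    "DegenerateImageError",
    "LabeledMask",
    "EllipseFit",
    "ShapeRecord",
    "as_gray",
    "threshold_max_entropy",
    "threshold_huang",
    "binarize",
    "extract_rois",
    "fit_ellipse_moments",
    "feret_diameters",
    "measure_shape",
    "measure_image",
    "records_to_frame",
]

# 4 sqrt(1/12): ellipse axis equivalent of a one-pixel-wide line
_ONE_PIXEL_AXIS = 4.0 * np.sqrt(1.0 / 12.0)


class DegenerateImageError(ValueError):
    """Raised when an image cannot be thresholded (e.g. constant intensity)."""


@dataclass(frozen=True)
class LabeledMask:
    """A binary region of interest with its pixel calibration.

    Parameters
    ----------
    mask
        2-D boolean array; True marks object pixels. Must contain at least
        one foreground pixel.
    scale
        Pixels per centimetre (> 0).
    roi_id
        Identifier of the ROI within its source image (1-based, reading
        order).
    """

    mask: np.ndarray
    scale: float
    roi_id: int = 1

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not mask.any():
            raise ValueError("mask has no foreground pixels")
        if not self.scale > 0:
            raise ValueError("scale must be positive (pixels per cm)")
        object.__setattr__(self, "mask", mask)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a region (ImageJ 'fit ellipse')."""

    major_px: float
    minor_px: float
    orientation_deg: float  # from the +x (column) axis, in (-90, 90]
    degenerate: bool = False


@dataclass(frozen=True)
class ShapeRecord:
    """The twelve morphometric descriptors of one ROI, in calibrated units.

    Lengths are in cm, the area in cm^2; ``aspect_ratio`` (major/minor),
    ``circularity`` (4 pi area / perimeter^2), ``roundness``
    (4 area / (pi major^2)) and ``solidity`` (area / convex-hull area)
    are dimensionless.
    """

    area: float
    perimeter: float
    width: float
    height: float
    major: float
    minor: float
    feret: float
    min_feret: float
    aspect_ratio: float
    circularity: float
    roundness: float
    solidity: float
    roi_id: int = 1
    degenerate: bool = False

    DESCRIPTORS = (
        "area",
        "perimeter",
        "width",
        "height",
        "major",
        "minor",
        "feret",
        "min_feret",
        "aspect_ratio",
        "circularity",
        "roundness",
        "solidity",
    )

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("area must be positive")
        if self.minor > self.major * (1 + 1e-9):
            raise ValueError("minor axis exceeds major axis")


def as_gray(image: np.ndarray) -> np.ndarray:
    """Return a float 2-D intensity image in [0, 255].

    RGB(A) input is converted by luminance; an alpha channel is ignored.
    """
    arr = np.asarray(image)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ValueError(f"expected RGB(A) last axis, got shape {arr.shape}")
        arr = arr[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    arr = arr.astype(float)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr


def _histogram256(image: np.ndarray) -> np.ndarray:
    levels = np.clip(np.round(as_gray(image)), 0, 255).astype(np.int64)
    return np.bincount(levels.ravel(), minlength=256)


def threshold_max_entropy(image: np.ndarray) -> int:
    """Kapur maximum-entropy threshold of a 256-level histogram.

    Returns the level ``t`` maximizing the summed Shannon entropies of the
    background class (levels <= t) and foreground class (levels > t); both
    classes are guaranteed non-empty.

    Raises
    ------
    DegenerateImageError
        If the image has fewer than two distinct intensity levels.
    """
    hist = _histogram256(image)
    nonzero = np.flatnonzero(hist)
    if nonzero.size < 2:
        raise DegenerateImageError("image has fewer than 2 distinct intensities")
    p = hist / hist.sum()
    best_t, best_crit = -1, -np.inf
    cdf = np.cumsum(p)
    for t in range(nonzero[0], nonzero[-1]):
        p0, p1 = cdf[t], 1.0 - cdf[t]
        if p0 <= 0 or p1 <= 0:
            continue
        lo = p[: t + 1][p[: t + 1] > 0] / p0
        hi = p[t + 1 :][p[t + 1 :] > 0] / p1
        crit = -np.sum(lo * np.log(lo)) - np.sum(hi * np.log(hi))
        if crit > best_crit:
            best_crit, best_t = crit, t
    return int(best_t)


def threshold_huang(image: np.ndarray) -> int:
    """Huang & Wang fuzzy threshold of a 256-level histogram.

    Returns the level minimizing the image's measure of fuzziness: the
    Shannon entropy of fuzzy memberships u(g) = 1 / (1 + |g - mu_class| / C)
    with C the intensity range, classes split at the candidate level.

    Raises
    ------
    DegenerateImageError
        If the image has fewer than two distinct intensity levels.
    """
    hist = _histogram256(image)
    nonzero = np.flatnonzero(hist)
    if nonzero.size < 2:
        raise DegenerateImageError("image has fewer than 2 distinct intensities")
    g = np.arange(256, dtype=float)
    w = hist.astype(float)
    c_span = float(nonzero[-1] - nonzero[0])
    cw = np.cumsum(w)
    cwg = np.cumsum(w * g)
    best_t, best_fuzz = -1, np.inf
    for t in range(nonzero[0], nonzero[-1]):
        n0, n1 = cw[t], cw[-1] - cw[t]
        if n0 <= 0 or n1 <= 0:
            continue
        mu0 = cwg[t] / n0
        mu1 = (cwg[-1] - cwg[t]) / n1
        mu = np.where(g <= t, mu0, mu1)
        u = 1.0 / (1.0 + np.abs(g - mu) / c_span)
        # Shannon fuzziness; u is in [0.5, 1] so only the (1-u) term can hit 0
        one_minus = np.clip(1.0 - u, 1e-300, None)
        h_f = -(u * np.log(u) + one_minus * np.log(one_minus))
        fuzz = float(np.sum(w * h_f))
        if fuzz < best_fuzz:
            best_fuzz, best_t = fuzz, t
    return int(best_t)


def binarize(image: np.ndarray, level: int, dark_objects: bool = False) -> np.ndarray:
    """Split an image at ``level``; foreground is the bright class (> level)
    unless ``dark_objects`` is set, in which case it is the class <= level."""
    gray = as_gray(image)
    return gray <= level if dark_objects else gray > level


def extract_rois(
    mask: np.ndarray, min_area_px: int = 1, scale: float = 1.0
) -> list[LabeledMask]:
    """Extract 8-connected components of ``mask`` as individual ROIs.

    Components smaller than ``min_area_px`` are discarded. ROIs are returned
    in reading order (centroid top-left to bottom-right) and cropped to their
    bounding boxes; an empty list is returned when nothing survives.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = _skmeasure.label(mask, connectivity=2)
    props = [p for p in _skmeasure.regionprops(labels) if p.area >= min_area_px]
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    rois = []
    for i, p in enumerate(props, start=1):
        sub = labels[p.slice] == p.label
        rois.append(LabeledMask(mask=sub, scale=scale, roi_id=i))
    return rois


def _region_coords(mask: np.ndarray) -> np.ndarray:
    return np.argwhere(mask).astype(float)


def fit_ellipse_moments(m: LabeledMask) -> EllipseFit:
    """Fit the ellipse with the region's normalized second central moments.

    Axis lengths follow the ImageJ/regionprops convention (4 sqrt(eigenvalue)
    of the pixel-coordinate covariance); a 1-pixel-thin region gets its minor
    axis clamped to the one-pixel equivalent and is flagged degenerate.
    """
    coords = _region_coords(m.mask)
    if coords.shape[0] < 5:
        raise ValueError("need at least 5 foreground pixels for an ellipse fit")
    rows, cols = coords[:, 0], coords[:, 1]
    x = cols - cols.mean()
    y = rows - rows.mean()
    cxx, cyy, cxy = np.mean(x * x), np.mean(y * y), np.mean(x * y)
    common = np.sqrt(max((cxx - cyy) ** 2 / 4.0 + cxy**2, 0.0))
    lam1 = (cxx + cyy) / 2.0 + common
    lam2 = (cxx + cyy) / 2.0 - common
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    # y grows downward, so negate the cross moment for a CCW-from-x angle
    theta = 0.5 * np.degrees(np.arctan2(-2.0 * cxy, cxx - cyy))
    if theta <= -90.0:
        theta += 180.0
    degenerate = minor < _ONE_PIXEL_AXIS
    if degenerate:
        warnings.warn(
            "degenerate (1-pixel-thin) region: minor axis clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        minor = _ONE_PIXEL_AXIS
        major = max(major, minor)
    return EllipseFit(float(major), float(minor), float(theta), degenerate)


def _hull_points(coords: np.ndarray) -> np.ndarray:
    """Convex-hull vertices of a pixel-center point cloud (falls back to the
    full cloud for degenerate/collinear regions)."""
    if coords.shape[0] < 3:
        return coords
    try:
        hull = ConvexHull(coords)
    except QhullError:
        return coords
    return coords[hull.vertices]


def feret_diameters(m: LabeledMask, sweep_deg: float = 0.1) -> tuple[float, float]:
    """Maximum and minimum caliper (Feret) diameters in pixels.

    The maximum Feret is the exact largest pairwise distance between
    convex-hull pixel centers; the minimum Feret is the smallest projection
    width of the hull over a caliper sweep with ``sweep_deg`` granularity.
    """
    coords = _region_coords(m.mask)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 foreground pixels for Feret diameters")
    pts = _hull_points(coords)
    diff = pts[:, None, :] - pts[None, :, :]
    feret = float(np.sqrt((diff**2).sum(-1)).max())
    angles = np.deg2rad(np.arange(0.0, 180.0, sweep_deg))
    dirs = np.stack([np.cos(angles), np.sin(angles)], axis=1)
    proj = pts @ dirs.T  # (n_pts, n_angles)
    widths = proj.max(axis=0) - proj.min(axis=0)
    min_feret = float(widths.min())
    return feret, min_feret


def measure_shape(m: LabeledMask) -> ShapeRecord:
    """Measure the twelve shape descriptors of one ROI in calibrated units."""
    s = m.scale
    area_px = float(m.area_px)
    perim_px = float(_skmeasure.perimeter_crofton(m.mask, directions=4))
    rows = np.any(m.mask, axis=1)
    cols = np.any(m.mask, axis=0)
    height_px = float(np.flatnonzero(rows)[-1] - np.flatnonzero(rows)[0] + 1)
    width_px = float(np.flatnonzero(cols)[-1] - np.flatnonzero(cols)[0] + 1)
    ell = fit_ellipse_moments(m)
    feret_px, min_feret_px = feret_diameters(m)
    hull_area_px = convex_hull_area(m.mask)
    area = area_px / s**2
    perimeter = perim_px / s
    major, minor = ell.major_px / s, ell.minor_px / s
    rec = ShapeRecord(
        area=area,
        perimeter=perimeter,
        width=width_px / s,
        height=height_px / s,
        major=major,
        minor=minor,
        feret=feret_px / s,
        min_feret=min_feret_px / s,
        aspect_ratio=major / minor,
        circularity=4.0 * np.pi * area / perimeter**2,
        roundness=4.0 * area / (np.pi * major**2),
        solidity=min(area_px / hull_area_px, 1.0),
        roi_id=m.roi_id,
        degenerate=ell.degenerate,
    )
    return rec


def convex_hull_area(mask: np.ndarray) -> float:
    """Lattice-point count of the filled convex hull of ``mask``.

    Computed exactly from the hull polygon of pixel centers via the
    shoelace formula and Pick's theorem (count = A + B/2 + 1 for a lattice
    polygon with B boundary lattice points), so a convex region has
    solidity exactly 1.
    """
    from math import gcd

    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    hull = _hull_points(coords.astype(float))
    if hull.shape[0] < 3:
        return float(mask.sum())
    x, y = hull[:, 0], hull[:, 1]
    area2 = abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    boundary = sum(
        gcd(int(round(abs(x[i] - x[(i + 1) % len(x)]))),
            int(round(abs(y[i] - y[(i + 1) % len(y)]))))
        for i in range(len(x))
    )
    return area2 / 2.0 + boundary / 2.0 + 1.0


def measure_image(
    image: np.ndarray,
    scale: float,
    method: str = "max_entropy",
    min_area_px: int = 50,
    dark_objects: bool = True,
) -> list[ShapeRecord]:
    """Threshold an image, extract ROIs and measure every object.

    ``method`` is one of ``max_entropy`` (default for seeds) or ``huang``
    (default choice for pods); ``dark_objects`` marks the objects as the
    dark side of the threshold (seeds/pods on a light background).
    """
    thresholders = {"max_entropy": threshold_max_entropy, "huang": threshold_huang}
    try:
        level = thresholders[method](image)
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}") from None
    fg = binarize(image, level, dark_objects=dark_objects)
    return [measure_shape(roi) for roi in extract_rois(fg, min_area_px, scale)]


def records_to_frame(records, image_id: str = ""):
    """Tabulate ShapeRecords as a DataFrame matching the measurement CSV layout
    (columns image_id, roi_id, area_cm2, perimeter_cm, ..., solidity)."""
    import pandas as pd

    unit_suffix = {
        "area": "area_cm2",
        "perimeter": "perimeter_cm",
        "width": "width_cm",
        "height": "height_cm",
        "major": "major_cm",
        "minor": "minor_cm",
        "feret": "feret_cm",
        "min_feret": "min_feret_cm",
        "aspect_ratio": "ar",
        "circularity": "circularity",
        "roundness": "roundness",
        "solidity": "solidity",
    }
    rows = []
    for rec in records:
        row = {"image_id": image_id, "roi_id": rec.roi_id}
        row.update({unit_suffix[k]: getattr(rec, k) for k in ShapeRecord.DESCRIPTORS})
        rows.append(row)
    cols = ["image_id", "roi_id", *unit_suffix.values()]
    return pd.DataFrame(rows, columns=cols)
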