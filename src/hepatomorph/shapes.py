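"""Morphometric shape descriptors of a single binary particle.

Implements the classical particle-analysis feature set used in ultrasound
liver-contour morphometry: area/perimeter of the traced boundary polygon,
convex-hull solidity, rotating-calipers Feret diameters, the equal-area
moment-fitted ellipse (Major/Minor/Angle), bounding box, and the derived
ratios (Circularity, AspectRatio, Roundness).

All lengths are in pixels, areas in px²; angles are reported in degrees in
[0, 180), measured counter-clockwise from the +x axis in the conventional
y-up frame (image y-down angles are negated).  See :mod:`hepatomorph.maskops`
for the contour/perimeter conventions, which determine the scale of
Circularity.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon as _ShPolygon

from . import maskops

__all__ = [
    "ShapeFeatures",
    "FEATURE_COLUMNS",
    "area_perimeter",
    "convex_hull_solidity",
    "feret_diameters",
    "fit_ellipse",
    "bounding_box",
    "shape_features",
]

#: report column order (the classical particle-analysis naming)
FEATURE_COLUMNS = [
    "Angle", "Aspect ratio", "Area", "Circularity", "Feret", "FeretAngle",
    "FeretX", "FeretY", "Height", "Major", "MinFeret", "Minor", "Perimeter",
    "Roundness", "Solidity", "Width",
]


@dataclass(frozen=True)
class ShapeFeatures:
    """The 16-feature morphometric record for one particle."""

    Area: float
    Perimeter: float
    Circularity: float
    AspectRatio: float
    Solidity: float
    Feret: float
    FeretAngle: float
    FeretX: float
    FeretY: float
    MinFeret: float
    Major: float
    Minor: float
    Angle: float
    Height: float
    Width: float
    Roundness: float

    def to_dict(self) -> dict[str, float]:
        """Feature dict keyed by the classical report column names."""
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["Aspect ratio"] = d.pop("AspectRatio")
        return {k: d[k] for k in FEATURE_COLUMNS}


def _signed_area2(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def area_perimeter(contour: np.ndarray) -> tuple[float, float]:
    """Polygon area (shoelace) and arc-length perimeter of a closed contour.

    For traced contours every step is axial (length 1) or diagonal
    (length sqrt(2)); the closing edge back to the first vertex is included.

    Raises
    ------
    ValueError
        If the polygon is self-intersecting.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3 or contour.shape[1] != 2:
        raise ValueError("contour must be an (n>=3, 2) array of (x, y) vertices")
    if not _ShPolygon(contour).is_valid:
        raise ValueError("self-intersecting contour polygon")
    area = abs(_signed_area2(contour)) / 2.0
    diffs = contour - np.roll(contour, -1, axis=0)
    perimeter = float(np.sqrt((diffs ** 2).sum(axis=1)).sum())
    return area, perimeter


def _hull_vertices(contour: np.ndarray) -> np.ndarray:
    """Convex hull vertex polygon (counter-clockwise in raw coordinates)."""
    try:
        hull = ConvexHull(contour)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) contour: no convex hull") from exc
    return contour[hull.vertices]


def convex_hull_solidity(contour: np.ndarray) -> tuple[np.ndarray, float]:
    """Convex hull polygon of the contour and Solidity = Area / ConvexArea."""
    contour = np.asarray(contour, dtype=float)
    hull = _hull_vertices(contour)
    area = abs(_signed_area2(contour)) / 2.0
    hull_area = abs(_signed_area2(hull)) / 2.0
    if hull_area <= 0:
        raise ValueError("degenerate hull with zero area")
    return hull, area / hull_area


def _pair_angle_deg(p: np.ndarray, q: np.ndarray) -> float:
    """Orientation of segment pq in degrees, y-up frame, in [0, 180)."""
    ang = np.degrees(np.arctan2(-(q[1] - p[1]), q[0] - p[0])) % 180.0
    # collapse 180-epsilon rounding to 0
    return float(ang % 180.0)


def feret_diameters(
    contour: np.ndarray,
) -> tuple[float, float, float, float, float]:
    """Caliper (Feret) diameters of a contour.

    Returns
    -------
    (Feret, FeretAngle, FeretX, FeretY, MinFeret)
        ``Feret`` is the maximum pairwise vertex distance; ``FeretAngle`` its
        orientation in degrees, y-up, in [0, 180); ``(FeretX, FeretY)`` the
        first endpoint of the maximal pair (the leftmost endpoint, ties broken
        by smaller y); ``MinFeret`` is the minimum caliper width from rotating
        calipers over convex-hull edge directions.

    Ties between maximal pairs are broken by smallest angle, then smallest
    FeretX.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 2:
        raise ValueError("need at least 2 contour vertices")

    pts = np.unique(contour, axis=0)
    if len(pts) < 2:
        raise ValueError("degenerate single-point contour")

    collinear = False
    if len(pts) == 2:
        hull = pts
        collinear = True
    else:
        try:
            hull = _hull_vertices(pts)
        except ValueError:
            hull = pts
            collinear = True

    # max Feret over hull vertex pairs
    d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
    dmax2 = d2.max()
    feret = float(np.sqrt(dmax2))
    ii, jj = np.nonzero(d2 >= dmax2 * (1 - 1e-12))
    best = None  # (angle, feret_x, feret_y)
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        p, q = hull[i], hull[j]
        # first endpoint: leftmost, ties by smaller y
        a, b = sorted([tuple(p), tuple(q)])
        ang = _pair_angle_deg(np.asarray(a), np.asarray(b))
        key = (round(ang, 9), a[0], a[1])
        if best is None or key < best[0]:
            best = (key, ang, a)
    _, feret_angle, first = best
    feret_x, feret_y = float(first[0]), float(first[1])

    if collinear:
        min_feret = 0.0
    else:
        # rotating calipers: the minimum width is attained with a caliper
        # flush against some hull edge
        edges = np.roll(hull, -1, axis=0) - hull
        lengths = np.sqrt((edges ** 2).sum(axis=1))
        keep = lengths > 0
        units = edges[keep] / lengths[keep, None]
        # perpendicular distance of every hull vertex from each edge line
        rel = hull[None, :, :] - hull[keep][:, None, :]
        cross = units[:, 0, None] * rel[:, :, 1] - units[:, 1, None] * rel[:, :, 0]
        widths = np.abs(cross).max(axis=1)
        min_feret = float(widths.min())

    return feret, feret_angle, feret_x, feret_y, min_feret


def fit_ellipse(mask: np.ndarray) -> tuple[float, float, float]:
    """Best-fitting ellipse of a particle by second-order central moments.

    The orientation and axis ratio come from the eigendecomposition of the
    pixel covariance (with the 1/12 per-pixel square correction); the axes
    are then rescaled so the ellipse area equals the particle's pixel count
    (equal-area moment fit, the convention of the classical particle
    analyzer).

    Returns
    -------
    (Major, Minor, Angle)
        Full axis lengths in px, Major >= Minor; Angle of the major axis in
        degrees, y-up frame, in [0, 180).
    """
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    n = len(xs)
    if n == 0:
        raise ValueError("empty mask")
    if n == 1:
        raise ValueError("zero-variance region: single-pixel particle")
    xc, yc = xs.mean(), ys.mean()
    dx, dy = xs - xc, ys - yc
    # +1/12: each pixel is a unit square, not a point
    mxx = (dx ** 2).mean() + 1.0 / 12.0
    myy = (dy ** 2).mean() + 1.0 / 12.0
    mxy = (dx * dy).mean()

    common = np.sqrt((mxx - myy) ** 2 + 4.0 * mxy ** 2)
    lam1 = (mxx + myy + common) / 2.0
    lam2 = (mxx + myy - common) / 2.0
    if lam2 <= 0:
        raise ValueError("zero-variance region: degenerate moments")
    ratio = np.sqrt(lam1 / lam2)

    minor = 2.0 * np.sqrt(n / (np.pi * ratio))
    major = minor * ratio

    theta = 0.5 * np.arctan2(2.0 * mxy, mxx - myy)  # image frame, y down
    angle = (-np.degrees(theta)) % 180.0
    return float(major), float(minor), float(angle)


def bounding_box(mask: np.ndarray) -> tuple[float, float]:
    """(Width, Height) of the tight axis-aligned box, in pixel counts."""
    mask = np.asarray(mask, dtype=bool)
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask")
    return float(xs.max() - xs.min() + 1), float(ys.max() - ys.min() + 1)


def shape_features(
    mask: np.ndarray, min_size: int = maskops.DEFAULT_MIN_SIZE
) -> ShapeFeatures:
    """Assemble the full 16-feature record for a single-particle mask.

    The mask is reduced to its largest filled particle first.  Derived
    ratios: Circularity = min(1, 4π·Area/Perimeter²) (capped because the
    raster polygon perimeter is biased), Roundness = 4·Area/(π·Major²),
    AspectRatio = Major/Minor.
    """
    particle = maskops.largest_particle(mask, min_size=min_size)
    contour = maskops.trace_contour(particle)

    area, perimeter = area_perimeter(contour)
    _, solidity = convex_hull_solidity(contour)
    feret, feret_angle, feret_x, feret_y, min_feret = feret_diameters(contour)
    major, minor, angle = fit_ellipse(particle)
    width, height = bounding_box(particle)

    circularity = min(1.0, 4.0 * np.pi * area / perimeter ** 2)
    roundness = 4.0 * area / (np.pi * major ** 2)
    aspect_ratio = major / minor

    return ShapeFeatures(
        Area=area,
        Perimeter=perimeter,
        Circularity=circularity,
        AspectRatio=aspect_ratio,
        Solidity=solidity,
        Feret=feret,
        FeretAngle=feret_angle,
        FeretX=feret_x,
        FeretY=feret_y,
        MinFeret=min_feret,
        Major=major,
        Minor=minor,
        Angle=angle,
        Height=height,
        Width=width,
        Roundness=roundness,
    )
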