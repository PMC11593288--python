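"""Raster mask utilities: binarization, particle selection, contour tracing, padding, I/O.

Conventions used throughout the package
---------------------------------------
* Images and masks are ``numpy`` arrays indexed ``[row, col]`` = ``[y, x]``;
  x grows rightward, y grows downward, and coordinates refer to 0-based
  pixel centers.
* A contour is an ``(n, 2)`` float array of ``(x, y)`` pixel-center
  coordinates forming a closed simple polygon (the closing edge from the
  last vertex back to the first is implicit).
* Foreground components are 8-connected; background holes are 4-connected
  (the standard complementary pair).
* Traced contours pass through boundary *pixel centers*, so consecutive
  vertices are one axial (length 1) or one diagonal (length sqrt(2)) step
  apart.  All downstream perimeters and areas inherit this polygon
  convention; a filled s-by-s square therefore has traced perimeter
  4*(s-1) and polygon area (s-1)**2.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage import draw as skdraw

__all__ = [
    "binarize",
    "largest_particle",
    "trace_contour",
    "rasterize_contour",
    "pad_to_square",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
]

#: connectivity structure for 8-connected foreground labelling
_STRUCT8 = np.ones((3, 3), dtype=bool)

DEFAULT_MIN_SIZE = 64


def binarize(image: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold a grayscale image: a pixel is foreground iff intensity >= threshold.

    Parameters
    ----------
    image : ndarray
        2-D intensity raster with values in [0, 255].
    threshold : float
        Cut value in [0, 255].

    Returns
    -------
    ndarray of bool
    """
    if not 0 <= threshold <= 255:
        raise ValueError(f"threshold must lie in [0, 255], got {threshold!r}")
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    return image >= threshold


def largest_particle(mask: np.ndarray, min_size: int = DEFAULT_MIN_SIZE) -> np.ndarray:
    """Keep the largest 8-connected foreground component, holes filled.

    Interior holes (4-connected background regions not touching the image
    border) are filled so the particle is solid before morphometry.

    Raises
    ------
    ValueError
        If the mask is empty ("no particle") or the largest component is
        smaller than ``min_size`` pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no particle: mask has no foreground pixels")
    labels, n = ndi.label(mask, structure=_STRUCT8)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    if sizes[best] < min_size:
        raise ValueError(
            f"largest particle has {sizes[best]} px, below min_size={min_size}"
        )
    out = labels == best
    # default (cross-shaped) structure fills 4-connected holes
    return ndi.binary_fill_holes(out)


# Moore neighborhood in clockwise screen order (y down), as (dx, dy),
# starting from west.
_MOORE = [(-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1)]


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of a single filled particle.

    Moore-neighbor tracing with Jacob's stopping criterion, starting from
    the first foreground pixel in raster order.  The returned polygon runs
    through boundary pixel centers and is counter-clockwise in the y-down
    image frame.

    Parameters
    ----------
    mask : ndarray of bool
        A mask containing exactly one filled 8-connected component
        (apply :func:`largest_particle` first).

    Returns
    -------
    ndarray, shape (n, 2)
        Closed polygon vertices as (x, y); the first vertex is not repeated.

    Raises
    ------
    ValueError
        If the mask is empty, or the component is thinner than 2 px
        everywhere (zero-area "degenerate particle").
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no particle: mask has no foreground pixels")
    h, w = mask.shape

    def fg(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and mask[y, x]

    ys, xs = np.nonzero(mask)
    start = (int(xs[ys == ys.min()].min()), int(ys.min()))

    if mask.sum() == 1:
        raise ValueError("degenerate particle: single pixel has no contour")

    # Jacob's criterion: stop upon re-entering the start pixel from the
    # same backtrack direction as the initial one.
    vertices: list[tuple[int, int]] = []
    cur = start
    backtrack = (start[0] - 1, start[1])  # west of start is background
    start_backtrack = backtrack
    seen_states: set[tuple] = set()
    max_steps = 4 * mask.size
    for _ in range(max_steps):
        state = (cur, backtrack)
        if state in seen_states:  # filament loops never satisfy Jacob's stop
            break
        seen_states.add(state)
        vertices.append(cur)
        # index of the backtrack position in the Moore ring around cur
        dx, dy = backtrack[0] - cur[0], backtrack[1] - cur[1]
        k0 = _MOORE.index((dx, dy))
        nxt = None
        for j in range(1, 9):
            cand = _MOORE[(k0 + j) % 8]
            px, py = cur[0] + cand[0], cur[1] + cand[1]
            if fg(px, py):
                nxt = (px, py)
                prev = _MOORE[(k0 + j - 1) % 8]
                backtrack = (cur[0] + prev[0], cur[1] + prev[1])
                break
        if nxt is None:  # isolated pixel
            raise ValueError("degenerate particle: single pixel has no contour")
        if nxt == start and backtrack == start_backtrack:
            break
        cur = nxt
    else:
        raise RuntimeError("contour tracing did not terminate")

    poly = np.asarray(vertices, dtype=float)
    if len(poly) < 3:
        raise ValueError("degenerate particle: contour has fewer than 3 vertices")
    # zero enclosed area <=> the component is a 1-px filament everywhere
    x, y = poly[:, 0], poly[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    if abs(area2) < 1e-9:
        raise ValueError("degenerate particle: component thinner than 2 px")
    return poly


def rasterize_contour(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Fill a contour polygon back into a raster mask.

    Interior fill plus the polygon's own boundary pixels, so that
    ``trace_contour(rasterize_contour(c, s))`` is idempotent on traced
    contours.
    """
    contour = np.asarray(contour, dtype=float)
    rr, cc = skdraw.polygon(contour[:, 1], contour[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    rr, cc = skdraw.polygon_perimeter(
        contour[:, 1], contour[:, 0], shape=shape, clip=True
    )
    mask[rr, cc] = True
    return mask


def pad_to_square(image: np.ndarray, fill: float = 0) -> np.ndarray:
    """Pad an image with black (zero) pixels so it becomes square.

    The original content stays in the top-left corner; the padding band is
    appended to the bottom or to the right, whichever dimension is short.
    Already-square input is returned unchanged (same object).
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h == w:
        return image
    side = max(h, w)
    out = np.full((side, side) + image.shape[2:], fill, dtype=image.dtype)
    out[:h, :w] = image
    return out


# ---------------------------------------------------------------------------
# PNG/TIFF I/O (8-bit grayscale; masks stored as 0/255)

def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale image (PNG/TIFF/JPEG)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"))


def write_image(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = np.clip(image, 0, 255).astype(np.uint8)
    Image.fromarray(image, mode="L").save(path)


def read_mask(path, threshold: float = 128) -> np.ndarray:
    """Read a mask image; pixels >= threshold are foreground."""
    return read_image(path) >= threshold


def write_mask(path, mask: np.ndarray) -> None:
    write_image(path, np.asarray(mask, dtype=bool).astype(np.uint8) * 255)
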