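"""Liver-surface roughness analysis from contour polylines.

The fibrotic liver develops irregularities on the dorsal (rear) surface of
the left lobe.  This module splits a lobe contour into front and rear
polylines, renders contour-only images, applies the bounded affine
augmentation used for the rough class, and scores roughness with a
deterministic statistic: the RMS perpendicular residual of the polyline
against its moving-average-smoothed version.  The statistic plus a
calibrated threshold stands in for a learned smooth/rough classifier and is
fully auditable; any external scorer returning a float can be plugged into
the same evaluation.

Also provides the focal loss ``FL(p_t) = -(1 - p_t)^gamma * ln(p_t)`` used
when a neural classifier is trained on these contour images under class
imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw

__all__ = [
    "SidePolyline",
    "AffineParams",
    "RoughnessScore",
    "ClassifierReport",
    "split_front_rear",
    "render_contour_image",
    "affine_augment",
    "focal_loss",
    "roughness_score",
    "calibrate_threshold",
    "evaluate_classifier",
    "DEFAULT_SMOOTH_WINDOW",
    "DEFAULT_ROUGH_THRESHOLD",
]

DEFAULT_SMOOTH_WINDOW = 31
#: default decision threshold (px RMS), sited between the raster staircase
#: noise floor of a smooth traced contour (~0.4 px) and the scores of
#: perturbed rear surfaces; recalibrate with :func:`calibrate_threshold` on a
#: labeled set when available.
DEFAULT_ROUGH_THRESHOLD = 0.5


@dataclass(frozen=True)
class SidePolyline:
    """An open polyline covering one side (front or rear) of a contour."""

    vertices: np.ndarray  # (n, 2) float, (x, y)
    side: str  # "front" | "rear"


@dataclass(frozen=True)
class AffineParams:
    """Bounded rotation/translation augmentation parameters (no scaling)."""

    rotation_deg: float
    shift_x_frac: float
    shift_y_frac: float

    MAX_ROT = 10.0
    MAX_SHIFT = 0.10

    def validate(self) -> None:
        if abs(self.rotation_deg) > self.MAX_ROT:
            raise ValueError(f"rotation must lie in ±{self.MAX_ROT} degrees")
        if abs(self.shift_x_frac) > self.MAX_SHIFT or abs(self.shift_y_frac) > self.MAX_SHIFT:
            raise ValueError(f"translations must lie in ±{self.MAX_SHIFT} of a dimension")

    @classmethod
    def random(cls, seed: int) -> "AffineParams":
        rng = np.random.default_rng(seed)
        return cls(
            rotation_deg=float(rng.uniform(-cls.MAX_ROT, cls.MAX_ROT)),
            shift_x_frac=float(rng.uniform(-cls.MAX_SHIFT, cls.MAX_SHIFT)),
            shift_y_frac=float(rng.uniform(-cls.MAX_SHIFT, cls.MAX_SHIFT)),
        )


@dataclass(frozen=True)
class RoughnessScore:
    rms_residual: float
    call: str  # "smooth" | "rough"
    threshold: float


@dataclass(frozen=True)
class ClassifierReport:
    """Per-class and overall accuracy, in percent (1 decimal)."""

    smooth_acc_pct: float
    rough_acc_pct: float
    overall_acc_pct: float
    n_smooth: int
    n_rough: int


def split_front_rear(contour: np.ndarray) -> tuple[SidePolyline, SidePolyline]:
    """Cut a closed contour at its leftmost and rightmost vertices.

    Ties in x are broken by the topmost (smallest y) vertex.  Of the two
    resulting polylines (which share both cut vertices), the one with the
    greater mean y — the deeper one in the y-down image frame — is the rear
    (dorsal) side.

    Raises
    ------
    ValueError
        If the contour spans fewer than 3 px horizontally.
    """
    contour = np.asarray(contour, dtype=float)
    n = len(contour)
    if n < 3:
        raise ValueError("contour must have at least 3 vertices")
    x = contour[:, 0]
    if x.max() - x.min() < 2:
        raise ValueError("no lateral extent: contour narrower than 3 px")

    def extreme(select_max: bool) -> int:
        xv = -x if select_max else x
        cands = np.nonzero(xv == xv.min())[0]
        return int(cands[np.argmin(contour[cands, 1])])

    i_left = extreme(False)
    i_right = extreme(True)

    def arc(i0: int, i1: int) -> np.ndarray:
        if i0 <= i1:
            return contour[i0 : i1 + 1]
        return np.vstack([contour[i0:], contour[: i1 + 1]])

    a = arc(i_left, i_right)
    b = arc(i_right, i_left)
    if a[:, 1].mean() >= b[:, 1].mean():
        rear_v, front_v = a, b
    else:
        rear_v, front_v = b, a
    return (
        SidePolyline(vertices=front_v, side="front"),
        SidePolyline(vertices=rear_v, side="rear"),
    )


def render_contour_image(
    front: SidePolyline, rear: SidePolyline, dims: tuple[int, int]
) -> np.ndarray:
    """Draw the two side polylines as 1-px white curves on a black canvas."""
    h, w = dims
    canvas = np.zeros(dims, dtype=np.uint8)
    for poly in (front, rear):
        v = np.asarray(poly.vertices, dtype=float)
        if (v[:, 0].min() < 0 or v[:, 1].min() < 0
                or v[:, 0].max() > w - 1 or v[:, 1].max() > h - 1):
            raise ValueError(f"{poly.side} polyline has vertices outside the canvas")
        vi = np.rint(v).astype(int)
        for (x0, y0), (x1, y1) in zip(vi[:-1], vi[1:]):
            rr, cc = skdraw.line(y0, x0, y1, x1)
            canvas[rr, cc] = 255
    return canvas


def affine_augment(
    image: np.ndarray,
    params: AffineParams | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Rotate about the image center and translate; no scaling.

    Nearest-neighbor resampling; content leaving the canvas is dropped and
    entering pixels are black.  The translation is
    ``(shift_x_frac * W, shift_y_frac * H)`` pixels.  When ``params`` is
    omitted they are drawn uniformly within the ±10° / ±10% bounds from
    ``seed``.
    """
    if params is None:
        if seed is None:
            raise ValueError("provide either explicit params or a seed")
        params = AffineParams.random(seed)
    params.validate()
    image = np.asarray(image)
    h, w = image.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ty = params.shift_y_frac * h
    tx = params.shift_x_frac * w
    ang = np.radians(params.rotation_deg)
    cos, sin = np.cos(ang), np.sin(ang)
    # inverse map: output (y, x) -> input coordinates
    rot_inv = np.array([[cos, sin], [-sin, cos]])
    center = np.array([cy, cx])
    shift = np.array([ty, tx])
    offset = center - rot_inv @ (center) + rot_inv @ (-shift)
    return ndi.affine_transform(
        image, rot_inv, offset=offset, order=0, mode="constant", cval=0,
        output=image.dtype,
    )


def focal_loss(p_t: float, gamma: float = 2.0) -> float:
    """Focal loss ``-(1 - p_t)^gamma * ln(p_t)`` (natural logarithm).

    Reduces to the cross-entropy ``-ln(p_t)`` at gamma = 0 and to 0 for a
    perfect prediction (p_t = 1).
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    if not 0 < p_t <= 1:
        raise ValueError("p_t must lie in (0, 1]")
    return float(-((1.0 - p_t) ** gamma) * np.log(p_t))


def _resample_arclength(vertices: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing."""
    seg = np.sqrt(((np.diff(vertices, axis=0)) ** 2).sum(axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    grid = np.arange(0.0, total, step)
    x = np.interp(grid, s, vertices[:, 0])
    y = np.interp(grid, s, vertices[:, 1])
    return np.column_stack([x, y])


def roughness_score(
    polyline: SidePolyline | np.ndarray,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    threshold: float = DEFAULT_ROUGH_THRESHOLD,
) -> RoughnessScore:
    """Score surface roughness of a polyline.

    The polyline is resampled at 1-px arc-length spacing and smoothed with a
    centered moving average of ``smooth_window`` samples; the score is the
    root-mean-square component of the residual perpendicular to the smoothed
    curve (the tangential component carries no surface-irregularity
    information).  The endpoints, where the moving average is undefined, are
    trimmed.

    A sinusoidal corrugation of amplitude A with wavelength well below the
    window scores approximately A/sqrt(2); a straight or slowly-curving
    segment scores near 0.

    The smooth/rough call compares the score against ``threshold``.

    Raises
    ------
    ValueError
        If the polyline's arc length is below ``3 * smooth_window``.
    """
    vertices = polyline.vertices if isinstance(polyline, SidePolyline) else polyline
    vertices = np.asarray(vertices, dtype=float)
    if smooth_window < 3:
        raise ValueError("smooth_window must be >= 3")
    if smooth_window % 2 == 0:
        smooth_window += 1
    pts = _resample_arclength(vertices)
    if len(pts) < 3 * smooth_window:
        raise ValueError(
            f"polyline too short: arc length {len(pts)} < 3*window={3 * smooth_window}"
        )
    kernel = np.full(smooth_window, 1.0 / smooth_window)
    sx = np.convolve(pts[:, 0], kernel, mode="valid")
    sy = np.convolve(pts[:, 1], kernel, mode="valid")
    half = smooth_window // 2
    core = pts[half : half + len(sx)]

    tx = np.gradient(sx)
    ty = np.gradient(sy)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    res_x = core[:, 0] - sx
    res_y = core[:, 1] - sy
    perp = (res_x * ty - res_y * tx) / norm
    rms = float(np.sqrt(np.mean(perp ** 2)))
    call = "rough" if rms >= threshold else "smooth"
    return RoughnessScore(rms_residual=rms, call=call, threshold=threshold)


def calibrate_threshold(scores, labels) -> float:
    """Pick the score threshold maximizing balanced accuracy on a labeled set.

    Candidates are midpoints between adjacent sorted scores; ties favor the
    smallest threshold.  Labels are "smooth"/"rough" strings.
    """
    scores = np.asarray(scores, dtype=float)
    rough = np.asarray([lab == "rough" for lab in labels])
    if rough.all() or not rough.any():
        raise ValueError("calibration set must contain both classes")
    order = np.sort(np.unique(scores))
    cands = np.concatenate([[order[0] - 1.0], (order[:-1] + order[1:]) / 2.0,
                            [order[-1] + 1.0]])
    best_t, best_bal = None, -np.inf
    for t in cands:
        call_rough = scores >= t
        sens = (call_rough & rough).sum() / rough.sum()
        spec = (~call_rough & ~rough).sum() / (~rough).sum()
        bal = (sens + spec) / 2.0
        if bal > best_bal + 1e-12:
            best_bal, best_t = bal, float(t)
    return best_t


def evaluate_classifier(calls, labels) -> ClassifierReport:
    """Accuracy among smooth-labeled, among rough-labeled, and overall (%).

    Order-invariant; percentages are rounded to one decimal.
    """
    calls = list(calls)
    labels = list(labels)
    if len(calls) != len(labels):
        raise ValueError("calls and labels must have equal length")
    for v in (*calls, *labels):
        if v not in ("smooth", "rough"):
            raise ValueError(f"invalid class value {v!r}")
    lab = np.asarray(labels)
    cal = np.asarray(calls)
    if not (("smooth" in labels) and ("rough" in labels)):
        raise ValueError("both classes must be represented in labels")
    smooth = lab == "smooth"
    rough = ~smooth
    smooth_acc = 100.0 * (cal[smooth] == "smooth").mean()
    rough_acc = 100.0 * (cal[rough] == "rough").mean()
    overall = 100.0 * (cal == lab).mean()
    return ClassifierReport(
        smooth_acc_pct=round(float(smooth_acc), 1),
        rough_acc_pct=round(float(rough_acc), 1),
        overall_acc_pct=round(float(overall), 1),
        n_smooth=int(smooth.sum()),
        n_rough=int(rough.sum()),
    )
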