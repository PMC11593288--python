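"""Synthetic cohorts of sagittal left-liver-lobe-like masks and images.

Clinical B-mode images of the left hepatic lobe are not publicly
deposited, so this module generates stand-in data with *known* geometry:
a superellipse base shape (two-parameter control of margin bluntness),
sheared slightly toward the caudal edge to mimic the wedge profile of a
sagittal section, with an optional sinusoidal perturbation of the rear
(dorsal) half of the boundary — the side where surface irregularity
appears with advancing fibrosis.  A speckle-textured pseudo-B-mode image
can be rendered from each mask.

The cohort generator injects two stage-dependent effects:

* the minor (short) axis of the lobe shrinks by a fixed fraction per
  fibrosis stage step (left-lobe thinning with advancing fibrosis), and
* the probability of a rough rear surface rises with stage.

Defaults follow the reference study population: 43 subjects with stage
counts 5/11/13/11/3 (F0..F4) and an overall rough:smooth prevalence of
roughly 27:73.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage as ndi

from . import maskops

__all__ = [
    "ShapeParams",
    "CohortConfig",
    "CohortRecord",
    "make_liver_shape",
    "render_bmode",
    "generate_cohort",
    "DEFAULT_STAGE_COUNTS",
    "DEFAULT_ROUGH_PROBS",
]

#: stage counts F0..F4 of the reference biopsy cohort
DEFAULT_STAGE_COUNTS = (5, 11, 13, 11, 3)

#: per-stage probability of a rough rear surface.  The study prints only the
#: pooled prevalence (~27% rough); these defaults rise with stage and pool to
#: 26.4% under the default stage counts.
DEFAULT_ROUGH_PROBS = (0.05, 0.15, 0.25, 0.40, 0.60)


@dataclass(frozen=True)
class ShapeParams:
    """Ground-truth geometry of one synthetic lobe section.

    Parameters
    ----------
    semi_major, semi_minor : float
        Superellipse semi-axes in px, ``semi_major >= semi_minor > 0``.
    bluntness : float
        Superellipse exponent p in ``|x/a|^p + |y/b|^p = 1``; p=2 is an
        ellipse, larger p gives blunter (boxier) margins.  Must be >= 1.
    rough_amplitude : float
        Peak amplitude (px) of the rear-surface perturbation; 0 = smooth.
        Must stay below ``semi_minor / 2``.
    rough_n_waves : int
        Number of random-phase sinusoids composing the perturbation.
    rotation_deg : float
        In-plane rotation, degrees counter-clockwise (y-up frame).
    center : (float, float)
        (x, y) center in pixel coordinates.
    shear : float
        Horizontal shear factor applied before rotation (wedge toward the
        caudal edge).
    """

    semi_major: float
    semi_minor: float
    bluntness: float = 2.5
    rough_amplitude: float = 0.0
    rough_n_waves: int = 0
    rotation_deg: float = 0.0
    center: tuple[float, float] = (256.0, 256.0)
    shear: float = 0.08

    def validate(self) -> None:
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError(
                f"degenerate axes: need semi_major >= semi_minor > 0, got "
                f"({self.semi_major}, {self.semi_minor})"
            )
        if self.bluntness < 1:
            raise ValueError("bluntness exponent must be >= 1")
        if self.rough_amplitude < 0:
            raise ValueError("rough_amplitude must be >= 0")
        if self.rough_amplitude >= self.semi_minor / 2:
            raise ValueError("rough_amplitude must be < semi_minor / 2")
        if self.rough_n_waves < 0:
            raise ValueError("rough_n_waves must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration of a synthetic cohort."""

    counts_per_stage: tuple[int, int, int, int, int] = DEFAULT_STAGE_COUNTS
    minor_shrink_per_stage: float = 0.10
    rough_prob_per_stage: tuple[float, ...] = DEFAULT_ROUGH_PROBS
    canvas: tuple[int, int] = (512, 512)
    seed: int = 0
    # baseline geometry (stage F0), px on the default 512-canvas
    semi_major_mean: float = 170.0
    semi_major_sd: float = 12.0
    semi_minor_mean: float = 88.0
    semi_minor_sd: float = 8.0

    def validate(self) -> None:
        if len(self.counts_per_stage) != 5 or any(
            c < 0 for c in self.counts_per_stage
        ):
            raise ValueError("counts_per_stage must be 5 nonnegative integers")
        if sum(self.counts_per_stage) < 1:
            raise ValueError("cohort must contain at least one subject")
        if len(self.rough_prob_per_stage) != 5 or any(
            not 0 <= p <= 1 for p in self.rough_prob_per_stage
        ):
            raise ValueError("rough_prob_per_stage must be 5 probabilities in [0,1]")
        if self.canvas[0] < 16 or self.canvas[1] < 16:
            raise ValueError("canvas too small")


@dataclass(frozen=True)
class CohortRecord:
    """One synthetic subject: labels, rasters, and ground-truth geometry."""

    subject_id: str
    stage: int
    rough_label: str  # "smooth" | "rough"
    mask: np.ndarray
    image: np.ndarray
    truth: ShapeParams


def _superellipse(theta: np.ndarray, a: float, b: float, p: float):
    cx = np.sign(np.cos(theta)) * np.abs(np.cos(theta)) ** (2.0 / p)
    cy = np.sign(np.sin(theta)) * np.abs(np.sin(theta)) ** (2.0 / p)
    return a * cx, b * cy


def make_liver_shape(
    params: ShapeParams,
    canvas: tuple[int, int] = (512, 512),
    seed: int = 0,
    n_vertices: int = 720,
    rasterize: bool = True,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Build one lobe-like closed contour and its filled raster mask.

    The base curve is the superellipse ``|x/a|^p + |y/b|^p = 1``; the rear
    half (y > 0 in the unrotated y-down frame, i.e. the deeper/dorsal side)
    is displaced along the outward normal by a sum of ``rough_n_waves``
    random-phase sinusoids, amplitude-normalized to ``rough_amplitude`` and
    windowed to vanish at the lateral tips.  The curve is then sheared,
    rotated, centered, and rasterized.

    Deterministic given ``(params, seed)``.

    Returns
    -------
    (contour, mask)
        ``contour``: (n, 2) float array of (x, y) vertices; ``mask``: filled
        boolean raster of shape ``canvas`` (``None`` when ``rasterize`` is
        false; the canvas-fit check still runs).

    Raises
    ------
    ValueError
        On degenerate axes or a shape that does not fit inside the canvas.
    """
    params.validate()
    h, w = canvas
    rng = np.random.default_rng(seed)

    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x, y = _superellipse(theta, params.semi_major, params.semi_minor,
                         params.bluntness)

    if params.rough_amplitude > 0 and params.rough_n_waves > 0:
        phases = rng.uniform(0, 2 * np.pi, size=params.rough_n_waves)
        weights = rng.uniform(0.5, 1.0, size=params.rough_n_waves)
        s = np.zeros_like(theta)
        for j in range(params.rough_n_waves):
            s += weights[j] * np.sin((2 * (j + 1)) * theta + phases[j])
        rear = (theta > 0) & (theta < np.pi)  # y > 0: dorsal half
        window = np.where(rear, np.sin(theta) ** 2, 0.0)
        smax = np.abs(s[rear] * window[rear]).max()
        delta = params.rough_amplitude * (s * window) / smax
        # outward normal from the tangent of the closed curve
        tx = np.gradient(x)
        ty = np.gradient(y)
        norm = np.hypot(tx, ty)
        nx, ny = ty / norm, -tx / norm
        # orient outward (away from origin)
        flip = (nx * x + ny * y) < 0
        nx = np.where(flip, -nx, nx)
        ny = np.where(flip, -ny, ny)
        x = x + delta * nx
        y = y + delta * ny

    x = x + params.shear * y

    ang = np.radians(params.rotation_deg)
    # CCW in the y-up frame == CW in raw y-down pixel coordinates
    xr = np.cos(ang) * x + np.sin(ang) * y
    yr = -np.sin(ang) * x + np.cos(ang) * y

    cx, cy = params.center
    xr = xr + cx
    yr = yr + cy

    if xr.min() < 1 or yr.min() < 1 or xr.max() > w - 2 or yr.max() > h - 2:
        raise ValueError("shape exceeds canvas after rotation")

    contour = np.column_stack([xr, yr])
    if not rasterize:
        return contour, None
    # 2x-supersampled scanline fill with majority pooling: PIL's fill is
    # inclusive by about half a pixel, supersampling halves that bias
    ss = 2
    img = Image.new("1", (w * ss, h * ss), 0)
    ImageDraw.Draw(img).polygon(
        [(ss * float(px), ss * float(py)) for px, py in contour], fill=1
    )
    fine = np.asarray(img, dtype=np.uint8)
    mask = fine.reshape(h, ss, w, ss).sum(axis=(1, 3)) >= (ss * ss) // 2 + 1
    return contour, ndi.binary_fill_holes(mask)


def render_bmode(mask: np.ndarray, seed: int = 0) -> np.ndarray:
    """Render a pseudo-B-mode grayscale image from a mask.

    Foreground parenchyma is mid-gray with correlated multiplicative
    Rayleigh speckle, background is darker with the same texture, and a
    bright 1–2 px capsule line runs along the boundary.  This emulates the
    gross intensity structure of tissue-harmonic B-mode images; it is not a
    wave-propagation simulation.

    Raises
    ------
    ValueError
        If the mask is empty, or has no background (all-foreground: no
        capsule line can be drawn).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if mask.all():
        raise ValueError("mask has no background: capsule line undefined")
    rng = np.random.default_rng(seed)

    speckle = rng.rayleigh(scale=1.0, size=mask.shape)
    speckle = ndi.gaussian_filter(speckle, sigma=1.2)
    speckle /= speckle.mean()

    img = np.where(mask, 140.0, 38.0) * speckle

    boundary = mask & ~ndi.binary_erosion(mask)
    capsule = ndi.binary_dilation(boundary)
    img[capsule] = 235.0 * (0.85 + 0.15 * speckle[capsule])

    return np.clip(img, 0, 255).astype(np.uint8)


def _draw_params(
    rng: np.random.Generator, config: CohortConfig, stage: int
) -> ShapeParams:
    h, w = config.canvas
    scale = min(h, w) / 512.0
    a = rng.normal(config.semi_major_mean, config.semi_major_sd) * scale
    base_b = rng.normal(config.semi_minor_mean, config.semi_minor_sd) * scale
    b = base_b * (1.0 - config.minor_shrink_per_stage * stage)
    b = float(np.clip(b, 18.0 * scale, 0.8 * a))
    rough = rng.random() < config.rough_prob_per_stage[stage]
    amplitude = float(rng.uniform(4.0, 9.0) * scale) if rough else 0.0
    n_waves = int(rng.integers(6, 12)) if rough else 0
    return ShapeParams(
        semi_major=float(a),
        semi_minor=b,
        bluntness=float(rng.uniform(2.3, 2.7)),
        rough_amplitude=amplitude,
        rough_n_waves=n_waves,
        rotation_deg=float(rng.uniform(-8.0, 8.0)),
        center=(
            w / 2.0 + float(rng.uniform(-12.0, 12.0) * scale),
            h / 2.0 + float(rng.uniform(-12.0, 12.0) * scale),
        ),
    )


def generate_cohort(
    config: CohortConfig,
    render_images: bool = True,
    rasterize: bool = True,
) -> list[CohortRecord]:
    """Generate a full cohort of synthetic subjects.

    Stage counts follow ``config.counts_per_stage``; each subject's minor
    semi-axis is a baseline draw shrunk by ``minor_shrink_per_stage`` per
    stage step, and the rough-surface label is Bernoulli with the per-stage
    probability.  Fully reproducible for a fixed config (byte-identical
    masks and images).

    Parameters
    ----------
    config : CohortConfig
    render_images : bool
        Skip the speckle rendering (faster) when only masks are needed.
    rasterize : bool
        When false, records carry ``mask=None`` and an all-zero image: only
        the ground-truth parameters and labels are produced.  The random
        stream is identical either way, so the truth values match a full
        run with the same config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[CohortRecord] = []
    idx = 0
    for stage, count in enumerate(config.counts_per_stage):
        for _ in range(count):
            params = None
            for _attempt in range(50):
                cand = _draw_params(rng, config, stage)
                shape_seed = int(rng.integers(0, 2 ** 31))
                try:
                    cand.validate()
                    contour, mask = make_liver_shape(
                        cand, canvas=config.canvas, seed=shape_seed,
                        rasterize=rasterize,
                    )
                except ValueError:
                    continue
                params = cand
                break
            if params is None:
                raise RuntimeError(
                    f"could not fit a stage-{stage} shape on canvas {config.canvas}"
                )
            img_seed = int(rng.integers(0, 2 ** 31))
            image = (
                render_bmode(mask, seed=img_seed)
                if (render_images and rasterize)
                else np.zeros(config.canvas, dtype=np.uint8)
            )
            records.append(
                CohortRecord(
                    subject_id=f"S{idx:03d}",
                    stage=stage,
                    rough_label="rough" if params.rough_amplitude > 0 else "smooth",
                    mask=mask,
                    image=image,
                    truth=params,
                )
            )
            idx += 1
    return records
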