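"""Shared fixtures: analytic raster shapes and small synthetic cohorts."""

import numpy as np
import pytest

from hepatomorph import synth


def raster_disk(r: int, pad: int = 4) -> np.ndarray:
    """Boolean raster of a disc of radius r (pixel center strictly inside)."""
    n = 2 * r + 2 * pad + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2
    return (xx - c) ** 2 + (yy - c) ** 2 <= r * r


def raster_ellipse(a: int, b: int, pad: int = 4) -> np.ndarray:
    """Axis-aligned raster ellipse with semi-axes (a, b) = (x, y)."""
    h, w = 2 * b + 2 * pad + 1, 2 * a + 2 * pad + 1
    yy, xx = np.mgrid[0:h, 0:w]
    return ((xx - w // 2) / a) ** 2 + ((yy - h // 2) / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def disk50():
    return raster_disk(50)


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-subject cohort (2/2/2/2/2) with masks and images, fixed seed."""
    cfg = synth.CohortConfig(counts_per_stage=(2, 2, 2, 2, 2), seed=11)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort_masks():
    """The default 43-subject cohort, masks only (no speckle rendering)."""
    cfg = synth.CohortConfig(seed=7)
    return synth.generate_cohort(cfg, render_images=False)
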