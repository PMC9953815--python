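"""Synthetic mammogram-like phantoms and Gaussian mixture point clouds.

Real screening mammograms have no pixel-exact lesion ground truth, which
makes them unsuitable for unit-testing a segmenter.  The generators here
produce images whose lesion and pectoral-muscle masks are known exactly:

* a smooth, low-frequency textured background (so clustering is not
  trivially a two-level threshold),
* bright elliptical lesions at a controlled contrast above the mean
  background,
* an optional bright pectoral-muscle triangle anchored at the top-left
  corner, as it appears in a correctly oriented MLO view,
* additive zero-mean Gaussian noise.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["Phantom", "MixtureSample", "generate_phantom", "generate_mixture"]

# Background base level and texture amplitude, in the native intensity
# units of a 10-bit-like mammogram.  Texture stays well below the default
# lesion contrast of ~30 so the lesion cluster remains identifiable.
_BG_BASE = 120.0
_BG_TEXTURE_AMPLITUDE = 10.0
_MUSCLE_MARGIN = 40.0  # muscle sits this far above the lesion intensity


@dataclass(frozen=True)
class Phantom:
    """A synthetic image with exact lesion / pectoral-muscle masks."""

    image: np.ndarray
    lesion_mask: np.ndarray
    muscle_mask: np.ndarray
    params: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image.shape != self.lesion_mask.shape or self.image.shape != self.muscle_mask.shape:
            raise InvalidArgumentError("image and masks must share one shape")
        for m in (self.lesion_mask, self.muscle_mask):
            if not np.isin(m, (0, 1)).all():
                raise InvalidArgumentError("masks must be strictly {0,1}")
        if np.logical_and(self.lesion_mask, self.muscle_mask).any():
            raise InvalidArgumentError("lesion and muscle masks must be disjoint")


@dataclass(frozen=True)
class MixtureSample:
    """Labelled isotropic Gaussian mixture draw with its true centers."""

    points: np.ndarray  # (n, dim)
    labels: np.ndarray  # (n,) ints in [0, c)
    true_centers: np.ndarray  # (c, dim)
    seed: int = 0

    def __post_init__(self) -> None:
        c = self.true_centers.shape[0]
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= c:
            raise InvalidArgumentError("labels must index rows of true_centers")
        if self.points.shape[0] < c or c < 1:
            raise InvalidArgumentError("need n >= c >= 1")


def _smooth_background(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of a few seeded low-frequency sinusoids over a base level."""
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    yy /= height
    xx /= width
    n_waves = int(rng.integers(2, 5))
    bg = np.full((height, width), _BG_BASE)
    for _ in range(n_waves):
        fy, fx = rng.uniform(0.5, 2.0, size=2)  # cycles over the image
        phase = rng.uniform(0.0, 2 * np.pi)
        amp = rng.uniform(0.3, 1.0) * _BG_TEXTURE_AMPLITUDE / n_waves
        bg += amp * np.sin(2 * np.pi * (fy * yy + fx * xx) + phase)
    return bg


def _pectoral_triangle(height: int, width: int) -> np.ndarray:
    """Right triangle at the top-left corner: legs 0.45*W along the top row
    and 0.45*H down the left column."""
    leg_x = max(2, int(round(0.45 * width)))
    leg_y = max(2, int(round(0.45 * height)))
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    return ((xx / leg_x + yy / leg_y) <= 1.0).astype(np.uint8)


def generate_phantom(
    height: int,
    width: int,
    n_lesions: int,
    lesion_contrast: float,
    noise_sigma: float,
    with_pectoral: bool = False,
    seed: int = 0,
) -> Phantom:
    """Generate a phantom image with known lesion and muscle masks.

    Lesions are filled ellipses whose intensity is ``lesion_contrast``
    above the mean background computed over all non-lesion pixels, so
    in the noiseless image the inside/outside mean difference equals the
    requested contrast exactly.

    Parameters
    ----------
    height, width : int
        Image size; at least 32 x 32.
    n_lesions : int
        Number of non-overlapping elliptical lesions, >= 0.
    lesion_contrast : float
        Intensity step of the lesions above the mean background.
    noise_sigma : float
        Scale of additive zero-mean Gaussian noise; 0 disables it.
    with_pectoral : bool
        Add a bright pectoral-muscle triangle at the top-left corner.
    seed : int
        Seeds every random choice; equal arguments give bit-identical
        phantoms.
    """
    if height < 32 or width < 32:
        raise InvalidArgumentError("height and width must both be >= 32")
    if n_lesions < 0:
        raise InvalidArgumentError("n_lesions must be >= 0")
    if noise_sigma < 0:
        raise InvalidArgumentError("noise_sigma must be >= 0")

    rng = np.random.default_rng(seed)
    image = _smooth_background(height, width, rng)
    muscle_mask = (
        _pectoral_triangle(height, width) if with_pectoral else np.zeros((height, width), np.uint8)
    )

    lesion_mask = np.zeros((height, width), np.uint8)
    lesion_geoms: list[dict[str, float]] = []
    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    placed = 0
    attempts = 0
    max_attempts = 200 * max(1, n_lesions)
    min_r = min(height, width) / 16.0
    max_r = min(height, width) / 8.0
    while placed < n_lesions:
        attempts += 1
        if attempts > max_attempts:
            raise InvalidArgumentError(
                f"could not place {n_lesions} non-overlapping lesions in a "
                f"{height}x{width} image"
            )
        a = rng.uniform(min_r, max_r)  # semi-axes in pixels
        b = rng.uniform(min_r, max_r)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b) + 2
        if height - margin <= margin or width - margin <= margin:
            raise InvalidArgumentError("lesions cannot fit in the requested image")
        cy = rng.uniform(margin, height - margin)
        cx = rng.uniform(margin, width - margin)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        ellipse = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)
        if np.logical_and(ellipse, muscle_mask).any():
            continue
        if np.logical_and(ellipse, lesion_mask).any():
            continue
        lesion_mask |= ellipse
        lesion_geoms.append(
            {"cy": float(cy), "cx": float(cx), "a": float(a), "b": float(b), "theta": float(theta)}
        )
        placed += 1

    bg_mean = float(image[lesion_mask == 0].mean())
    image = image.copy()
    image[lesion_mask == 1] = bg_mean + lesion_contrast
    if with_pectoral:
        image[muscle_mask == 1] = bg_mean + lesion_contrast + _MUSCLE_MARGIN

    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)

    params = {
        "height": height,
        "width": width,
        "n_lesions": n_lesions,
        "lesion_contrast": float(lesion_contrast),
        "noise_sigma": float(noise_sigma),
        "with_pectoral": bool(with_pectoral),
        "lesions": lesion_geoms,
    }
    return Phantom(image=image, lesion_mask=lesion_mask, muscle_mask=muscle_mask,
                   params=params, seed=seed)


def generate_mixture(
    n: int,
    c: int,
    dim: int,
    separation: float,
    noise_sigma: float,
    seed: int = 0,
) -> MixtureSample:
    """Draw a balanced isotropic Gaussian mixture with well-separated centers.

    Centers are rejection-sampled in a box scaled to ``separation`` until
    every pairwise distance is at least ``separation``.  Labels are
    balanced round-robin (group sizes differ by at most one) and each
    point is its center plus isotropic N(0, noise_sigma^2) noise.
    """
    if c < 1 or n < c:
        raise InvalidArgumentError("need n >= c >= 1")
    if separation <= 0 or noise_sigma <= 0:
        raise InvalidArgumentError("separation and noise_sigma must be > 0")

    rng = np.random.default_rng(seed)
    box = separation * max(2.0, c ** (1.0 / dim) * 1.5)
    centers = np.empty((c, dim))
    placed = 0
    for _ in range(10000):
        cand = rng.uniform(0.0, box, size=dim)
        if placed == 0 or np.linalg.norm(centers[:placed] - cand, axis=1).min() >= separation:
            centers[placed] = cand
            placed += 1
            if placed == c:
                break
    if placed < c:
        raise InvalidArgumentError("failed to place separated centers; lower c or separation")

    labels = np.arange(n) % c
    points = centers[labels] + rng.normal(0.0, noise_sigma, size=(n, dim))
    return MixtureSample(points=points, labels=labels, true_centers=centers, seed=seed)
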