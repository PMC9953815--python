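"""Mammogram preprocessing: intensity normalization, orientation, pectoral removal.

The pipeline expects images whose breast tissue sits in the lower half of
the frame (CC view) or whose pectoral-muscle wedge sits in a top corner
(MLO view).  Preprocessing therefore has three steps:

1. z-score the intensities and rescale affinely to [0, 1024] — a strictly
   monotone map, so no ordering information is lost;
2. decide whether a vertical flip is needed, from the view label;
3. for MLO views, segment the bright pectoral wedge touching the top
   corner (Otsu threshold + corner-connected component) and zero it out.
"""

from __future__ import annotations

import enum

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "ViewLabel",
    "CornerLocation",
    "INTENSITY_RANGE",
    "normalize_intensity",
    "needs_flip",
    "locate_pectoral_corner",
    "remove_pectoral_muscle",
]

INTENSITY_RANGE = 1024.0  # normalized images live in [0, INTENSITY_RANGE]

# Fraction of min(H, W) used for the corner windows when locating the
# pectoral muscle; 1/4 is large enough to catch the wedge, small enough
# not to swallow central tissue.
_CORNER_FRACTION = 0.25


class ViewLabel(enum.Enum):
    CC = "cc"
    MLO = "mlo"


class CornerLocation(enum.Enum):
    TOP_LEFT = "top_left"
    TOP_RIGHT = "top_right"
    BOTTOM_LEFT = "bottom_left"
    BOTTOM_RIGHT = "bottom_right"

    @property
    def is_top(self) -> bool:
        return self in (CornerLocation.TOP_LEFT, CornerLocation.TOP_RIGHT)


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Z-score then affinely rescale so min -> 0 and max -> 1024.

    The composition of the two affine maps is itself affine, hence
    strictly monotone: pixel ranking is preserved, and applying the map
    twice equals applying it once.

    Raises
    ------
    DegenerateInputError
        If the image has zero intensity variance.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InvalidArgumentError("empty image")
    std = image.std()
    if std == 0:
        raise DegenerateInputError(
            "image has zero intensity variance (constant image); cannot normalize"
        )
    z = (image - image.mean()) / std
    return (z - z.min()) / (z.max() - z.min()) * INTENSITY_RANGE


def needs_flip(image: np.ndarray, view: ViewLabel) -> bool:
    """Whether the image must be flipped vertically to be right side up.

    CC view: flip when the top half carries strictly more intensity mass
    than the bottom half (tissue should sit at the bottom).  For an odd
    row count the middle row belongs to neither half.
    MLO view: flip when the pectoral wedge is found in a bottom corner.
    """
    image = np.asarray(image, dtype=float)
    if image.shape[0] < 2:
        raise InvalidArgumentError("needs_flip requires at least 2 rows")
    if view is ViewLabel.CC:
        half = image.shape[0] // 2
        return float(image[:half].sum()) > float(image[-half:].sum())
    corner = locate_pectoral_corner(image)
    return not corner.is_top


def locate_pectoral_corner(image: np.ndarray) -> CornerLocation:
    """Corner whose k x k window has the greatest mean intensity.

    k = ceil(min(H, W) / 4).  Ties break in the fixed order TOP_LEFT,
    TOP_RIGHT, BOTTOM_LEFT, BOTTOM_RIGHT.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    if h < 8 or w < 8:
        raise InvalidArgumentError("locate_pectoral_corner requires an image of at least 8x8")
    k = int(np.ceil(min(h, w) * _CORNER_FRACTION))
    windows = [
        (CornerLocation.TOP_LEFT, image[:k, :k]),
        (CornerLocation.TOP_RIGHT, image[:k, -k:]),
        (CornerLocation.BOTTOM_LEFT, image[-k:, :k]),
        (CornerLocation.BOTTOM_RIGHT, image[-k:, -k:]),
    ]
    best = windows[0][0]
    best_mean = windows[0][1].mean()
    for corner, win in windows[1:]:
        m = win.mean()
        if m > best_mean:
            best, best_mean = corner, m
    return best


def remove_pectoral_muscle(
    image: np.ndarray, corner: CornerLocation
) -> tuple[np.ndarray, np.ndarray]:
    """Suppress the pectoral wedge touching the given top corner.

    The muscle is taken as the connected component of pixels at or above
    the Otsu threshold that contains the corner pixel; those pixels are
    set to 0.  If the corner pixel is below threshold the image is
    returned unchanged with an empty mask.

    Returns ``(cleaned image, muscle_mask)`` with the mask in {0, 1}.
    """
    image = np.asarray(image, dtype=float)
    if not corner.is_top:
        raise InvalidArgumentError(
            "remove_pectoral_muscle expects a TOP corner; flip the image first"
        )
    thresh = threshold_otsu(image)
    bright = image >= thresh
    corner_idx = (0, 0) if corner is CornerLocation.TOP_LEFT else (0, image.shape[1] - 1)
    mask = np.zeros(image.shape, np.uint8)
    if bright[corner_idx]:
        comps = cc_label(bright, connectivity=2)
        mask = (comps == comps[corner_idx]).astype(np.uint8)
    cleaned = image.copy()
    cleaned[mask == 1] = 0.0
    return cleaned, mask
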