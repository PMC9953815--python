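"""Grayscale PGM/PNG reading and writing.

Mini-MIAS-style mammograms ship as PGM; PNG is supported for
convenience.  Images round-trip losslessly for 8/16-bit integer data;
binary masks are written as {0, 255} and read back as {0, 1}.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .errors import UnsupportedFormatError

__all__ = ["read_image", "write_image", "read_mask", "write_mask"]

_SUFFIXES = {".pgm", ".png"}


def _check_path(path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in _SUFFIXES:
        raise UnsupportedFormatError(f"unsupported image format: {path.suffix!r}")
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PGM (P2/P5) or PNG as a 2-D float array."""
    path = _check_path(path)
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA", "P", "CMYK", "YCbCr"):
            raise UnsupportedFormatError(
                f"{path.name}: color images are not supported (mode {im.mode})"
            )
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path.name}: expected a single-channel image")
    return arr.astype(float)


def write_image(grid: np.ndarray, path: str | Path) -> None:
    """Write a 2-D array as 8- or 16-bit grayscale, chosen by value range.

    Float input is rounded to the nearest integer; values must fall in
    [0, 65535].
    """
    path = _check_path(path)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise UnsupportedFormatError("expected a 2-D grid")
    vals = np.rint(grid)
    if vals.min() < 0 or vals.max() > 65535:
        raise UnsupportedFormatError("pixel values outside [0, 65535]")
    if vals.max() <= 255:
        im = Image.fromarray(vals.astype(np.uint8), mode="L")
    else:
        im = Image.fromarray(vals.astype(np.uint16))
    im.save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask; any nonzero pixel becomes 1."""
    arr = read_image(path)
    return (arr > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0,1} mask as a {0, 255} 8-bit image."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise UnsupportedFormatError("mask must be strictly {0,1}")
    write_image(mask.astype(np.uint8) * 255, path)
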