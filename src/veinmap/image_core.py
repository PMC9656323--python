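"""Image carriers and file I/O.

Every stage of the pipeline consumes and produces 8-bit grayscale images
("gray images"), represented as 2-D ``numpy.uint8`` arrays in raster order
(row 0 at top, 0-based ``(row, col)`` indexing).  Stage-internal arithmetic
may run in a wider real-valued carrier ("wide images"); the single point of
truth for getting back to 8 bits is :func:`from_wide`, which clips to
[0, 255] and rounds half-up so results are bit-reproducible across
platforms.

Masks are 2-D boolean arrays aligned with their gray image; on disk they
are PNGs encoding False/True as 0/255.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio

__all__ = [
    "as_gray",
    "as_mask",
    "to_wide",
    "from_wide",
    "read_gray",
    "write_gray",
    "read_mask",
    "write_mask",
]

#: luma weights for collapsing RGB inputs (ITU-R BT.601)
_LUMA = np.array([0.299, 0.587, 0.114])


def as_gray(pixels) -> np.ndarray:
    """Validate and return *pixels* as a 2-D uint8 gray image.

    Raises ``ValueError`` if the array is not 2-D, is empty, or holds
    values outside [0, 255].
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2:
        raise ValueError(f"gray image must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("gray image must have height >= 1 and width >= 1")
    if arr.dtype != np.uint8:
        if np.any((arr < 0) | (arr > 255)):
            raise ValueError("gray image values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def as_mask(pixels, like: np.ndarray | None = None) -> np.ndarray:
    """Validate and return *pixels* as a 2-D boolean mask.

    If *like* is given the mask must match its shape.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"mask must be a non-empty 2-D array, got shape {arr.shape}")
    arr = arr.astype(bool, copy=False)
    if like is not None and arr.shape != like.shape:
        raise ValueError(f"mask shape {arr.shape} != image shape {like.shape}")
    return arr


def to_wide(img: np.ndarray) -> np.ndarray:
    """Promote an 8-bit image to the wide (float64) working carrier."""
    return as_gray(img).astype(np.float64)


def from_wide(wide: np.ndarray) -> np.ndarray:
    """Clip a wide image to [0, 255] and round half-up to uint8."""
    arr = np.asarray(wide, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("wide image must be a non-empty 2-D array")
    # floor(x + 0.5) is round-half-up; np.round would round half-to-even
    return np.floor(np.clip(arr, 0.0, 255.0) + 0.5).astype(np.uint8)


def read_gray(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG or PGM file as an 8-bit gray image.

    Color inputs are collapsed by luma; 16-bit inputs are rescaled to
    8-bit (65535 -> 255, round half-up).
    """
    arr = iio.imread(path)
    if arr.size == 0:
        raise ValueError(f"{path}: zero-sized image")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr[:, :, :3].astype(np.float64) @ _LUMA
    elif arr.ndim != 2:
        raise ValueError(f"{path}: unsupported image dimensionality {arr.ndim}")
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) * (255.0 / 65535.0)
    return from_wide(arr.astype(np.float64))


def write_gray(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write an 8-bit gray image as PNG or PGM (chosen by extension)."""
    img = as_gray(img)
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext in (".pgm", ".ppm", ".pnm"):
        _write_pgm(img, path)
    else:
        iio.imwrite(path, img)


def _write_pgm(img: np.ndarray, path: str | os.PathLike) -> None:
    h, w = img.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{w} {h}\n255\n".encode("ascii"))
        fh.write(img.tobytes())


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a 0/255-encoded mask PNG; any nonzero pixel counts as True."""
    return read_gray(path) > 0


def write_mask(mask: np.ndarray, path: str | os.PathLike) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    mask = as_mask(mask)
    write_gray(np.where(mask, 255, 0).astype(np.uint8), path)
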