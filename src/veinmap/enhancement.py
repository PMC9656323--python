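"""The six-stage vein visibility pipeline.

Stages, in order: lighting removal, histogram normalization, histogram
equalization, Otsu-based noise thresholding (bright non-vein texture is
flattened to 255; veins — the dark structures — pass through untouched),
grayscale dilation of the dark vein component to reconnect broken
segments, unsharp sharpening to restore stroke thickness, and median
smoothing.  Every stage is exposed individually; `enhance` wires them.

All stages are deterministic, so a fixed input and configuration yield a
bit-identical vein map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .hair_removal import HairParams, otsu_threshold, remove_hair
from .illumination import IlluminationParams, remove_light
from .image_core import as_gray, from_wide
from .morphology import StructuringElement, cross3, gray_dilate, gray_erode

__all__ = [
    "EnhanceParams",
    "hist_normalize",
    "hist_equalize",
    "noise_threshold",
    "sharpen",
    "median_smooth",
    "enhance",
    "enhance_stages",
]

# 3x3 binomial kernel, the fixed Gaussian approximation used by sharpen
_GAUSS3 = np.array([[1, 2, 1], [2, 4, 2], [1, 2, 1]], dtype=np.float64) / 16.0


@dataclass(frozen=True)
class EnhanceParams:
    illumination: IlluminationParams = field(default_factory=IlluminationParams)
    hair: HairParams = field(default_factory=HairParams)
    norm_range: tuple[int, int] = (0, 255)
    dilate_se: StructuringElement = field(default_factory=cross3)
    dilate_iters: int = 1
    #: "bright" is the plain max-filter dilation (shrinks dark specks and
    #: trims vein edges); "dark" is the min-filter variant that grows the
    #: dark vein component instead
    dilate_polarity: str = "bright"
    sharpen_amount: float = 1.0
    median_size: int = 3

    def __post_init__(self):
        lo, hi = self.norm_range
        if not (0 <= lo < hi <= 255):
            raise ValueError(f"norm_range must satisfy 0 <= min < max <= 255, got {self.norm_range}")
        if self.median_size % 2 == 0 or self.median_size < 1:
            raise ValueError(f"median_size must be odd >= 1, got {self.median_size}")
        if self.sharpen_amount < 0:
            raise ValueError("sharpen_amount must be >= 0")
        if self.dilate_polarity not in ("dark", "bright"):
            raise ValueError(f"dilate_polarity must be 'dark' or 'bright', got {self.dilate_polarity!r}")


def hist_normalize(img: np.ndarray, min_n: int = 0, max_n: int = 255) -> np.ndarray:
    """Linear stretch of the image's actual range onto [min_n, max_n].

    ``I_N = (I - Min) * (MaxN - MinN) / (Max - Min) + MinN``; a constant
    image maps to ``min_n``.
    """
    img = as_gray(img)
    if not min_n < max_n:
        raise ValueError("min_n must be < max_n")
    lo, hi = int(img.min()), int(img.max())
    if lo == hi:
        return np.full_like(img, min_n)
    scaled = (img.astype(np.float64) - lo) * (max_n - min_n) / (hi - lo) + min_n
    return from_wide(scaled)


def hist_equalize(img: np.ndarray) -> np.ndarray:
    """Cumulative-histogram equalization: ``i -> cumhist(i) / n * 255``."""
    img = as_gray(img)
    hist = np.bincount(img.ravel(), minlength=256)
    cum = np.cumsum(hist).astype(np.float64)
    lut = from_wide((cum / img.size * 255.0)[np.newaxis, :])[0]
    return lut[img]


def noise_threshold(img: np.ndarray) -> np.ndarray:
    """Flatten everything brighter than the Otsu threshold to 255.

    Pixels at or below the threshold (the dark vein component) are kept
    bit-identical.
    """
    img = as_gray(img)
    t = otsu_threshold(img)
    return np.where(img > t, np.uint8(255), img)


def sharpen(img: np.ndarray, amount: float = 1.0) -> np.ndarray:
    """Unsharp masking with a fixed 3x3 binomial blur (replicate border)."""
    img = as_gray(img)
    if amount < 0:
        raise ValueError("amount must be >= 0")
    wide = img.astype(np.float64)
    blurred = ndimage.correlate(wide, _GAUSS3, mode="nearest")
    return from_wide(wide + amount * (wide - blurred))


def median_smooth(img: np.ndarray, size: int = 3) -> np.ndarray:
    """Median filter over a size x size replicate-padded window."""
    img = as_gray(img)
    if size % 2 == 0 or size < 1:
        raise ValueError(f"size must be odd >= 1, got {size}")
    return ndimage.median_filter(img, size=size, mode="nearest")


def enhance_stages(
    img: np.ndarray,
    p: EnhanceParams = EnhanceParams(),
    hair_mode: bool = False,
) -> list[tuple[str, np.ndarray]]:
    """Run the pipeline, returning every named intermediate image."""
    img = as_gray(img)
    stages: list[tuple[str, np.ndarray]] = [("input", img)]

    def run(name: str, fn: Callable[[np.ndarray], np.ndarray], x: np.ndarray) -> np.ndarray:
        try:
            y = fn(x)
        except Exception as exc:
            raise RuntimeError(f"enhancement stage {name!r} failed: {exc}") from exc
        stages.append((name, y))
        return y

    x = img
    if hair_mode:
        x = run("hair_removal", lambda im: remove_hair(im, p.hair)[0], x)
    x = run("light_removal", lambda im: remove_light(im, p.illumination), x)
    x = run("normalize", lambda im: hist_normalize(im, *p.norm_range), x)
    x = run("equalize", hist_equalize, x)
    x = run("threshold", noise_threshold, x)
    dilate = gray_erode if p.dilate_polarity == "dark" else gray_dilate
    x = run("dilate", lambda im: dilate(im, p.dilate_se, iterations=p.dilate_iters), x)
    x = run("sharpen", lambda im: sharpen(im, p.sharpen_amount), x)
    x = run("median", lambda im: median_smooth(im, p.median_size), x)
    return stages


def enhance(img: np.ndarray, p: EnhanceParams = EnhanceParams(), hair_mode: bool = False) -> np.ndarray:
    """Full pipeline; returns the final 8-bit vein map (veins dark)."""
    return enhance_stages(img, p, hair_mode)[-1][1]
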