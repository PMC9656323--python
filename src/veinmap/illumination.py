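"""Nonuniform-lighting removal.

An NIR capture carries a low-frequency lighting gradient that breaks
threshold-based stages downstream.  The background (lighting) component is
estimated with a large mean filter; its "reverse" — the pointwise gap
between the image's global maximum and the background — is added back to
the image, flattening illumination while preserving local vein contrast.
The sum can exceed 255, so it runs in the wide carrier and is clipped at
the end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import as_gray, from_wide

__all__ = ["IlluminationParams", "mean_filter", "estimate_background", "remove_light"]


@dataclass(frozen=True)
class IlluminationParams:
    """Mean-filter window for background estimation; >= 31 px and odd."""

    blur_size: int = 31

    def __post_init__(self):
        if self.blur_size % 2 == 0:
            raise ValueError(f"blur_size must be odd, got {self.blur_size}")
        if self.blur_size < 31:
            raise ValueError(f"blur_size must be >= 31, got {self.blur_size}")


def mean_filter(img: np.ndarray, size: int) -> np.ndarray:
    """Real-valued size x size mean filter with replicate borders."""
    img = as_gray(img)
    if size % 2 == 0 or size < 1:
        raise ValueError(f"mean filter size must be odd >= 1, got {size}")
    # mode="nearest" replicates the edge row/column, matching the border
    # rule used everywhere else in the pipeline
    return ndimage.uniform_filter(img.astype(np.float64), size=size, mode="nearest")


def estimate_background(img: np.ndarray, p: IlluminationParams = IlluminationParams()) -> np.ndarray:
    """Background (lighting) estimate: large mean filter of the image."""
    return mean_filter(img, p.blur_size)


def remove_light(img: np.ndarray, p: IlluminationParams = IlluminationParams()) -> np.ndarray:
    """Flatten the lighting component.

    ``out = clip(img + (max(img) - background(img)))`` rounded to 8 bits.
    The reverse term is pointwise non-negative (the background never
    exceeds the global maximum), so the output dominates the input.
    """
    img = as_gray(img)
    reverse = float(img.max()) - estimate_background(img, p)
    return from_wide(img.astype(np.float64) + reverse)
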