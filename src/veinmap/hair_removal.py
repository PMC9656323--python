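"""Digital hair removal.

Hair strokes are thin, sharp-edged dark structures sitting directly on the
epidermis, so a Blackhat with a small structuring element responds to them
strongly while barely reacting to the wide, soft-edged veins underneath.
The response is binarized with Otsu's threshold, grown by binary dilation
so that the inpainting boundary rests on clean skin, and the resulting
holes are filled by fast-marching inpainting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_core import as_gray
from .inpainting import InpaintParams, telea_inpaint
from .morphology import StructuringElement, binary_dilate, binary_erode, blackhat, cross3

__all__ = ["HairParams", "otsu_threshold", "detect_hair_mask", "remove_hair"]


def diamond5() -> StructuringElement:
    """5x5 diamond (city-block radius 2), the default hair-detection SE.

    A 3x3 cross fits inside the diagonal rendering of a 2-px hair stroke,
    so a cross-SE closing cannot see it; the diamond is the smallest
    isotropic SE that reliably catches hair up to ~3 px wide at any
    orientation while remaining far narrower than a vein.
    """
    dy, dx = np.mgrid[-2:3, -2:3]
    return StructuringElement(np.abs(dy) + np.abs(dx) <= 2)


def diamond7() -> StructuringElement:
    """7x7 diamond (city-block radius 3); catches overlapping hair blobs."""
    dy, dx = np.mgrid[-3:4, -3:4]
    return StructuringElement(np.abs(dy) + np.abs(dx) <= 3)


@dataclass(frozen=True)
class HairParams:
    #: SE of the Blackhat detector (larger than the stroke width it must see)
    se: StructuringElement = field(default_factory=diamond7)
    #: SE used to grow the detected mask
    grow_se: StructuringElement = field(default_factory=cross3)
    #: binary dilations applied to the detected mask so the inpainting
    #: boundary clears the hair stroke
    mask_growth_iters: int = 2
    #: Blackhat responses at or below this floor never count as hair; keeps
    #: Otsu from splitting the pure-noise response of a hairless image
    min_response: float = 16.0
    #: drop isolated single-pixel detections with a binary opening first
    open_first: bool = False
    #: exclude zero Blackhat responses from the Otsu histogram
    otsu_exclude_zero: bool = False
    inpaint: InpaintParams = field(default_factory=InpaintParams)

    def __post_init__(self):
        if self.mask_growth_iters < 0:
            raise ValueError("mask_growth_iters must be >= 0")


def otsu_threshold(img: np.ndarray, exclude_zero: bool = False) -> int:
    """Otsu's threshold on the 256-bin histogram.

    Returns the smallest ``t`` maximizing the between-class variance of
    the split {<= t} / {> t}.  A constant image returns its single value
    (callers thresholding with ``> t`` then see an empty foreground).
    """
    img = as_gray(img)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    if exclude_zero:
        hist[0] = 0.0
    total = hist.sum()
    if total == 0:  # every pixel excluded
        return 0
    nz = np.nonzero(hist)[0]
    if nz.size == 1:
        return int(nz[0])
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels <= t
    sum0 = np.cumsum(hist * levels)
    mu = sum0[-1] / total
    w1 = total - w0
    # between-class variance; undefined where one class is empty
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = (mu * w0 - sum0) ** 2 / (w0 * w1)
    var_b[~np.isfinite(var_b)] = -np.inf
    return int(np.argmax(var_b))  # argmax takes the smallest maximizer


def detect_hair_mask(img: np.ndarray, p: HairParams = HairParams()) -> np.ndarray:
    """Blackhat -> Otsu binarize (> t) -> optional opening -> grow."""
    img = as_gray(img)
    response = blackhat(img, p.se)
    t = max(otsu_threshold(response, exclude_zero=p.otsu_exclude_zero), p.min_response)
    mask = response > t
    if p.open_first and mask.any():
        mask = binary_dilate(binary_erode(mask, p.grow_se), p.grow_se)
    if p.mask_growth_iters and mask.any():
        mask = binary_dilate(mask, p.grow_se, iterations=p.mask_growth_iters)
    return mask


def remove_hair(img: np.ndarray, p: HairParams = HairParams()) -> tuple[np.ndarray, np.ndarray]:
    """Return (hair-free image, hair mask used).

    An empty mask returns the input unchanged; a mask covering the whole
    image is surfaced as an error from the inpainting stage.
    """
    img = as_gray(img)
    mask = detect_hair_mask(img, p)
    if not mask.any():
        return img.copy(), mask
    try:
        filled = telea_inpaint(img, mask, p.inpaint)
    except ValueError as exc:
        raise ValueError(f"hair removal failed: {exc}") from exc
    return filled, mask
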