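"""Verification protocol: binarize pipeline outputs and score them against
the ground-truth vessel layer with SSIM, averaged over a dataset.

Both operands of the comparison are binarized and rendered as 0/255 gray
images, so the score is insensitive to which gray level the vessel layer
was drawn in.  SSIM follows the canonical form: 11x11 Gaussian window
(sigma 1.5), K1 = 0.01, K2 = 0.03, L = 255, Gaussian-weighted local
moments, mean taken over the valid (fully-windowed) region.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import convolve2d

from .enhancement import EnhanceParams, enhance
from .hair_removal import otsu_threshold
from .image_core import as_gray, read_gray, read_mask

__all__ = ["SSIMParams", "EvalReport", "binarize_output", "render_mask", "ssim", "evaluate_dataset"]


@dataclass(frozen=True)
class SSIMParams:
    window: int = 11
    sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 255.0

    def __post_init__(self):
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError(f"window must be odd >= 3, got {self.window}")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("K1 and K2 must be > 0")


@dataclass(frozen=True)
class EvalReport:
    per_image: list[tuple[str, float]]
    mean_ssim: float
    min_ssim: float
    max_ssim: float
    hair_mode: bool
    skipped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        pct = lambda v: round(100.0 * v, 2)
        return {
            "per_image": [{"id": i, "ssim": s, "ssim_pct": pct(s)} for i, s in self.per_image],
            "mean": self.mean_ssim,
            "min": self.min_ssim,
            "max": self.max_ssim,
            "mean_pct": pct(self.mean_ssim),
            "min_pct": pct(self.min_ssim),
            "max_pct": pct(self.max_ssim),
            "hair_mode": self.hair_mode,
            "skipped": list(self.skipped),
        }


def binarize_output(img: np.ndarray) -> np.ndarray:
    """Vein mask of an enhanced output: Otsu threshold, keep the dark side.

    Foreground is ``<= t``; a constant image is all-foreground.
    """
    img = as_gray(img)
    return img <= otsu_threshold(img)


def render_mask(mask: np.ndarray) -> np.ndarray:
    """Render a boolean mask as a 0/255 gray image for SSIM comparison."""
    return np.where(np.asarray(mask, dtype=bool), np.uint8(255), np.uint8(0))


def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    half = window // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(x * x) / (2.0 * sigma * sigma))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(a: np.ndarray, b: np.ndarray, p: SSIMParams = SSIMParams()) -> float:
    """Mean structural similarity between two gray images."""
    a = as_gray(a).astype(np.float64)
    b = as_gray(b).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < p.window:
        raise ValueError(f"images must be at least {p.window} pixels on each side")
    kernel = _gaussian_kernel(p.window, p.sigma)
    win = lambda x: convolve2d(x, kernel, mode="valid")
    mu_a, mu_b = win(a), win(b)
    var_a = win(a * a) - mu_a * mu_a
    var_b = win(b * b) - mu_b * mu_b
    cov = win(a * b) - mu_a * mu_b
    c1 = (p.k1 * p.dynamic_range) ** 2
    c2 = (p.k2 * p.dynamic_range) ** 2
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * cov + c2)
    den = (mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2)
    return float(np.mean(num / den))


def _dataset_ids(directory: str | os.PathLike) -> list[str]:
    return sorted(
        name
        for name in os.listdir(directory)
        if os.path.isfile(os.path.join(directory, name, "image.png"))
    )


def evaluate_dataset(
    directory: str | os.PathLike,
    params: EnhanceParams = EnhanceParams(),
    hair_mode: bool = False,
    ssim_params: SSIMParams = SSIMParams(),
) -> EvalReport:
    """Score every phantom in *directory* (one subdirectory per id, with
    ``image.png`` and ``vessel_mask.png`` / ``vessel_layer.png``).

    Each image is run through the pipeline, binarized, rendered 0/255 and
    compared to the 0/255 rendering of the ground-truth vessel mask.  Ids
    missing ground truth are listed as skipped; if nothing is scorable a
    ``ValueError`` is raised.
    """
    ids = _dataset_ids(directory)
    per_image: list[tuple[str, float]] = []
    skipped: list[str] = []
    for image_id in ids:
        sub = os.path.join(directory, image_id)
        mask_path = os.path.join(sub, "vessel_mask.png")
        layer_path = os.path.join(sub, "vessel_layer.png")
        if os.path.isfile(mask_path):
            truth = read_mask(mask_path)
        elif os.path.isfile(layer_path):
            truth = read_gray(layer_path) < 255
        else:
            skipped.append(image_id)
            continue
        img = read_gray(os.path.join(sub, "image.png"))
        out = enhance(img, params, hair_mode=hair_mode)
        score = ssim(render_mask(binarize_output(out)), render_mask(truth), ssim_params)
        per_image.append((image_id, score))
    if not per_image:
        raise ValueError(f"no scorable phantoms found under {directory}")
    scores = [s for _, s in per_image]
    return EvalReport(
        per_image=per_image,
        mean_ssim=float(np.mean(scores)),
        min_ssim=float(np.min(scores)),
        max_ssim=float(np.max(scores)),
        hair_mode=hair_mode,
        skipped=skipped,
    )
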