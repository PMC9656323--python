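"""Synthetic NIR phantom generator.

The real validation dataset behind this method is not public, so phantoms
stand in for it: a skin-textured base (flat level + smoothed noise +
planar lighting tilt + sensor noise), a ground-truth vessel layer drawn in
gray on white, an 85%-transparency composite of the two, and optional
thin dark hair strokes overdrawn on top.  Every layer the generator
composes is returned as ground truth, so downstream stages can be scored
exactly.

Randomness comes from ``numpy.random.default_rng`` (PCG64) seeded from
``PhantomSpec.seed``; each layer uses its own child stream, so e.g.
``draw_vessels`` is reproducible independently of the base texture.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_core import as_gray, from_wide, write_gray, write_mask

__all__ = ["PhantomSpec", "PhantomBundle", "make_base", "draw_vessels", "draw_hair", "composite", "make_phantom", "save_bundle"]

#: recorded image scale (the stroke widths equate 0.5-1 cm to 15-20 px);
#: nothing downstream consumes physical units
PX_PER_CM = 20


@dataclass(frozen=True)
class PhantomSpec:
    size: tuple[int, int] = (480, 640)
    skin_level: int = 160
    vessel_gray: int = 60          # nominal range 57-62
    vessel_width_px: int = 16      # nominal range 15-20
    n_vessels: int = 3
    vessel_wander: float = 0.08    # std-dev of heading change per step (rad)
    hair_count: int = 0
    hair_width_px: int = 2
    hair_gray: int = 40
    hair_wander: float = 0.15
    hair_area_frac: float | None = None  # draw hairs until this fraction is covered
    light_gradient: float = 40.0   # gray-level span of the planar tilt
    texture_amp: float = 1.0       # amplitude of smoothed-noise skin texture
    texture_scale: float = 12.0    # smoothing sigma of the texture field
    noise_sigma: float = 0.5       # per-pixel Gaussian sensor noise
    transparency: float = 0.85     # base-layer alpha in the composite
    seed: int = 0

    def __post_init__(self):
        h, w = self.size
        if h < 1 or w < 1:
            raise ValueError("size must be at least 1x1")
        if self.vessel_width_px < 1:
            raise ValueError("vessel_width_px must be >= 1")
        if self.hair_width_px < 1:
            raise ValueError("hair_width_px must be >= 1")
        if not 0.0 <= self.transparency <= 1.0:
            raise ValueError("transparency must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomBundle:
    image: np.ndarray
    vessel_layer: np.ndarray
    vessel_mask: np.ndarray
    hair_mask: np.ndarray
    hair_free_image: np.ndarray
    spec: PhantomSpec


def _rng(spec: PhantomSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _disk_offsets(width: int) -> np.ndarray:
    """Pixel offsets of the round brush stamped along a stroke path.

    The brush spans exactly *width* pixels: odd widths use a disk centred
    on a pixel, even widths a disk centred on a pixel corner.
    """
    r = width / 2.0
    if width % 2:
        n = (width - 1) // 2
        dy, dx = np.mgrid[-n : n + 1, -n : n + 1]
        keep = dy * dy + dx * dx <= r * r
    else:
        n = width // 2
        dy, dx = np.mgrid[-n + 1 : n + 1, -n + 1 : n + 1]
        keep = (dy - 0.5) ** 2 + (dx - 0.5) ** 2 <= r * r
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp_walk(mask: np.ndarray, points: np.ndarray, offsets: np.ndarray) -> None:
    """Mark the round-brush stroke through *points* on *mask* (in place)."""
    h, w = mask.shape
    pts = (points[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    keep = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
    pts = pts[keep]
    mask[pts[:, 0], pts[:, 1]] = True


def _walk(rng: np.random.Generator, shape, start, heading: float, wander: float, n_steps: int) -> np.ndarray:
    """Unit-step random walk with smoothly wandering heading; stops when it
    leaves the frame.  Returns integer (row, col) points."""
    h, w = shape
    pts = []
    y, x = float(start[0]), float(start[1])
    for _ in range(n_steps):
        pts.append((int(round(y)), int(round(x))))
        heading += wander * rng.standard_normal()
        y += np.sin(heading)
        x += np.cos(heading)
        if not (-1 <= y <= h and -1 <= x <= w):
            break
    return np.array(pts, dtype=np.int64).reshape(-1, 2)


def make_base(spec: PhantomSpec) -> np.ndarray:
    """Skin base: flat level + smoothed-noise texture + horizontal lighting
    tilt + per-pixel sensor noise."""
    h, w = spec.size
    rng = _rng(spec, 0)
    base = np.full((h, w), float(spec.skin_level))
    if spec.texture_amp > 0:
        field = rng.standard_normal((h, w))
        field = ndimage.gaussian_filter(field, sigma=spec.texture_scale, mode="nearest")
        sd = field.std()
        if sd > 0:
            base += field / sd * spec.texture_amp
    if spec.light_gradient != 0 and w > 1:
        base += spec.light_gradient * (np.arange(w) / (w - 1) - 0.5)
    if spec.noise_sigma > 0:
        base += rng.normal(0.0, spec.noise_sigma, size=(h, w))
    return from_wide(base)


def draw_vessels(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth vessel layer: gray strokes on a white (255) field."""
    h, w = spec.size
    rng = _rng(spec, 1)
    mask = np.zeros((h, w), dtype=bool)
    offsets = _disk_offsets(spec.vessel_width_px)
    for _ in range(spec.n_vessels):
        edge = rng.integers(4)
        if edge == 0:  # left
            start, heading = (rng.uniform(0.2, 0.8) * h, 0.0), 0.0
        elif edge == 1:  # right
            start, heading = (rng.uniform(0.2, 0.8) * h, w - 1.0), np.pi
        elif edge == 2:  # top
            start, heading = (0.0, rng.uniform(0.2, 0.8) * w), np.pi / 2
        else:  # bottom
            start, heading = (h - 1.0, rng.uniform(0.2, 0.8) * w), -np.pi / 2
        pts = _walk(rng, (h, w), start, heading, spec.vessel_wander, n_steps=2 * (h + w))
        _stamp_walk(mask, pts, offsets)
    layer = np.where(mask, np.uint8(spec.vessel_gray), np.uint8(255))
    return layer, mask


def draw_hair(img: np.ndarray, spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Overdraw thin, high-curvature dark strokes; returns (image, mask)."""
    img = as_gray(img)
    h, w = img.shape
    rng = _rng(spec, 2)
    mask = np.zeros((h, w), dtype=bool)
    offsets = _disk_offsets(spec.hair_width_px)
    n_steps = max(20, int(0.8 * min(h, w)))

    def one_stroke():
        start = (rng.uniform(0, h - 1), rng.uniform(0, w - 1))
        heading = rng.uniform(0, 2 * np.pi)
        pts = _walk(rng, (h, w), start, heading, spec.hair_wander, n_steps)
        _stamp_walk(mask, pts, offsets)

    if spec.hair_area_frac is not None:
        target = spec.hair_area_frac * mask.size
        while mask.sum() < target:
            one_stroke()
    else:
        for _ in range(spec.hair_count):
            one_stroke()
    out = img.copy()
    out[mask] = spec.hair_gray
    return out, mask


def composite(base: np.ndarray, vessel_layer: np.ndarray, alpha: float) -> np.ndarray:
    """Blend the vessel layer under an alpha-transparent base.

    ``out = round(alpha * base + (1 - alpha) * vessel_layer)``; the white
    vessel-layer background turns non-vessel pixels into a brightened
    base.
    """
    base = as_gray(base)
    vessel_layer = as_gray(vessel_layer)
    if base.shape != vessel_layer.shape:
        raise ValueError(f"shape mismatch: {base.shape} vs {vessel_layer.shape}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return from_wide(alpha * base.astype(np.float64) + (1.0 - alpha) * vessel_layer.astype(np.float64))


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> PhantomBundle:
    """Assemble the full bundle: base -> vessel composite -> hair overdraw."""
    base = make_base(spec)
    vessel_layer, vessel_mask = draw_vessels(spec)
    hair_free = composite(base, vessel_layer, spec.transparency)
    if spec.hair_count > 0 or spec.hair_area_frac is not None:
        image, hair_mask = draw_hair(hair_free, spec)
    else:
        image = hair_free.copy()
        hair_mask = np.zeros(spec.size, dtype=bool)
    return PhantomBundle(
        image=image,
        vessel_layer=vessel_layer,
        vessel_mask=vessel_mask,
        hair_mask=hair_mask,
        hair_free_image=hair_free,
        spec=spec,
    )


def save_bundle(bundle: PhantomBundle, directory: str | os.PathLike) -> None:
    """Write a bundle as the on-disk layout the evaluator consumes."""
    os.makedirs(directory, exist_ok=True)
    d = os.fspath(directory)
    write_gray(bundle.image, os.path.join(d, "image.png"))
    write_gray(bundle.vessel_layer, os.path.join(d, "vessel_layer.png"))
    write_gray(bundle.hair_free_image, os.path.join(d, "hair_free.png"))
    write_mask(bundle.vessel_mask, os.path.join(d, "vessel_mask.png"))
    write_mask(bundle.hair_mask, os.path.join(d, "hair_mask.png"))
    meta = dataclasses.asdict(bundle.spec)
    meta["px_per_cm"] = PX_PER_CM
    with open(os.path.join(d, "spec.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
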