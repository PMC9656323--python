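"""Fast-marching (Telea-style) inpainting.

Masked pixels are restored in increasing order of their distance to the
mask boundary, so every pixel is filled from already-known material.  The
distance field solves the unit-speed Eikonal equation on the 4-connected
grid: pixels touching the known region are seeded at distance 1 (their
exact Euclidean distance to the nearest known pixel centre) and deeper
pixels use the standard two-axis quadratic update.  The priority queue
breaks distance ties by (row, col), making the fill order — and therefore
the output — fully deterministic.

Each pixel is filled with a normalized weighted sum of known pixels within
a small radius; weights multiply a direction term (alignment of the offset
with the marching front's normal), an inverse-square geometric distance
term, and a level-set proximity term.  A plain inverse-distance-squared
mode is available as a documented simplification.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .image_core import as_gray, as_mask, from_wide

__all__ = ["InpaintParams", "boundary_distance", "telea_inpaint"]

_DIR_FLOOR = 0.01  # minimum direction weight; keeps weights positive


@dataclass(frozen=True)
class InpaintParams:
    """Fill neighborhood radius and weight mode ("telea" or "inverse")."""

    radius: int = 3
    weight_mode: str = "telea"

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError(f"radius must be >= 1, got {self.radius}")
        if self.weight_mode not in ("telea", "inverse"):
            raise ValueError(f"weight_mode must be 'telea' or 'inverse', got {self.weight_mode!r}")


def _eikonal_update(T: np.ndarray, final: np.ndarray, r: int, c: int) -> float:
    """Quadratic Eikonal update at (r, c) from finalized 4-neighbours."""
    h, w = T.shape
    a = np.inf  # best horizontal neighbour
    if c > 0 and final[r, c - 1]:
        a = T[r, c - 1]
    if c + 1 < w and final[r, c + 1]:
        a = min(a, T[r, c + 1])
    b = np.inf  # best vertical neighbour
    if r > 0 and final[r - 1, c]:
        b = T[r - 1, c]
    if r + 1 < h and final[r + 1, c]:
        b = min(b, T[r + 1, c])
    if np.isfinite(a) and np.isfinite(b) and abs(a - b) < 1.0:
        return (a + b + np.sqrt(2.0 - (a - b) ** 2)) / 2.0
    return min(a, b) + 1.0


def _march(mask: np.ndarray, on_finalize=None) -> np.ndarray:
    """Run FMM over the masked region; returns the distance field.

    ``on_finalize(r, c)`` is invoked as each masked pixel is frozen, in
    marching order.
    """
    h, w = mask.shape
    if mask.all():
        raise ValueError("mask covers the entire image; no boundary to march from")
    T = np.where(mask, np.inf, 0.0)
    final = ~mask  # known pixels are finalized at distance 0

    # seed: masked pixels with a known 4-neighbour sit exactly 1 away
    known = ~mask
    seed = mask & (
        np.pad(known, ((0, 1), (0, 0)))[1:, :]
        | np.pad(known, ((1, 0), (0, 0)))[:-1, :]
        | np.pad(known, ((0, 0), (0, 1)))[:, 1:]
        | np.pad(known, ((0, 0), (1, 0)))[:, :-1]
    )
    T[seed] = 1.0
    heap = [(1.0, int(r), int(c)) for r, c in zip(*np.nonzero(seed))]
    heapq.heapify(heap)

    while heap:
        t, r, c = heapq.heappop(heap)
        if final[r, c] or t > T[r, c]:
            continue
        final[r, c] = True
        if on_finalize is not None:
            on_finalize(r, c)
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] and not final[nr, nc] and not seed[nr, nc]:
                cand = _eikonal_update(T, final, nr, nc)
                if cand < T[nr, nc]:
                    T[nr, nc] = cand
                    heapq.heappush(heap, (cand, nr, nc))
    return T


def boundary_distance(mask: np.ndarray) -> np.ndarray:
    """Approximate Euclidean distance of each masked pixel to the known
    region (0 on unmasked pixels), by fast marching."""
    mask = as_mask(mask)
    return _march(mask)


def telea_inpaint(img: np.ndarray, mask: np.ndarray, p: InpaintParams = InpaintParams()) -> np.ndarray:
    """Fill masked pixels of *img* in fast-marching order.

    Unmasked pixels are returned bit-identical; filled values are convex
    combinations of known pixels so the output range never leaves the
    known range.
    """
    img = as_gray(img)
    mask = as_mask(mask, like=img)
    if not mask.any():
        return img.copy()

    R = p.radius
    pad = R + 1  # one extra cell for gradient windows at the border
    h, w = img.shape

    # first pass: distance field + deterministic fill order
    order: list[tuple[int, int]] = []
    T = _march(mask, on_finalize=lambda r, c: order.append((r, c)))

    # padded working arrays: outside-image cells are never usable
    work = np.pad(img.astype(np.float64), pad, mode="constant")
    usable = np.pad(~mask, pad, mode="constant", constant_values=False)
    Tpad = np.pad(T, pad, mode="constant", constant_values=np.inf)

    dy, dx = np.mgrid[-R : R + 1, -R : R + 1]
    lensq = (dy * dy + dx * dx).astype(np.float64)
    ring = (lensq > 0) & (lensq <= R * R)
    lensq[~ring] = 1.0  # dummy; excluded from every weighted sum
    inv_len = np.zeros_like(lensq)
    inv_len[ring] = 1.0 / np.sqrt(lensq[ring])

    def grad_T(r: int, c: int) -> tuple[float, float]:
        # central differences on the (padded) distance field, one-sided
        # next to unknown material, zero if isolated
        out = []
        for da, db in (((1, 0), (-1, 0)), ((0, 1), (0, -1))):
            tp = Tpad[r + pad + da[0], c + pad + da[1]]
            tm = Tpad[r + pad + db[0], c + pad + db[1]]
            t0 = Tpad[r + pad, c + pad]
            if np.isfinite(tp) and np.isfinite(tm):
                out.append((tp - tm) / 2.0)
            elif np.isfinite(tp):
                out.append(tp - t0)
            elif np.isfinite(tm):
                out.append(t0 - tm)
            else:
                out.append(0.0)
        return out[0], out[1]

    def known_gradients(win2):
        """Central/one-sided image gradients over the usable pixels of an
        expanded (2R+3)^2 window; 0 where no usable neighbour exists."""
        v = work[win2]
        u = usable[win2]
        grads = []
        for axis in (0, 1):

            def sl(shift):
                a = [slice(1, -1), slice(1, -1)]
                a[axis] = slice(1 + shift, v.shape[axis] - 1 + shift)
                return tuple(a)

            vp, vm, v0 = v[sl(1)], v[sl(-1)], v[sl(0)]
            up, um = u[sl(1)], u[sl(-1)]
            g = np.where(
                up & um, (vp - vm) / 2.0, np.where(up, vp - v0, np.where(um, v0 - vm, 0.0))
            )
            grads.append(g)
        return grads

    def fill(r: int, c: int) -> None:
        win = (slice(r + 1, r + 2 * R + 2), slice(c + 1, c + 2 * R + 2))
        sel = usable[win] & ring
        if not sel.any():  # cannot happen after marching from a seed
            return
        t0 = Tpad[r + pad, c + pad]
        if p.weight_mode == "telea":
            ny, nx = grad_T(r, c)
            norm = np.hypot(ny, nx)
            if norm > 0:
                ny, nx = ny / norm, nx / norm
            # offset p - q = -(dy, dx); positive alignment with the front
            # normal gets full weight, the floor keeps weights positive
            direction = np.maximum((-(ny * dy) - nx * dx) * inv_len, _DIR_FLOOR)
            level = 1.0 / (1.0 + np.abs(t0 - Tpad[win]))
            weights = (direction * level / lensq)[sel]
            # first-order extrapolation from each contributor toward p
            win2 = (slice(r, r + 2 * R + 3), slice(c, c + 2 * R + 3))
            gy, gx = known_gradients(win2)
            vals = (work[win] + gy * (-dy) + gx * (-dx))[sel]
        else:
            weights = (1.0 / lensq)[sel]
            vals = work[win][sel]
        raw = float(np.sum(weights * vals) / np.sum(weights))
        known_vals = work[win][sel]
        # clamp extrapolation overshoot: the fill stays a value between the
        # contributing known pixels, keeping global range preservation
        work[r + pad, c + pad] = min(max(raw, float(known_vals.min())), float(known_vals.max()))
        usable[r + pad, c + pad] = True

    for r, c in order:
        fill(r, c)

    out = work[pad : pad + h, pad : pad + w]
    result = from_wide(out)
    result[~mask] = img[~mask]  # guarantee bit-identity off the mask
    return result
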