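"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops straight from the
operator definitions, deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np


def se_offsets(kernel: np.ndarray, anchor: tuple[int, int]):
    offs = []
    for r in range(kernel.shape[0]):
        for c in range(kernel.shape[1]):
            if kernel[r, c]:
                offs.append((r - anchor[0], c - anchor[1]))
    return offs


def brute_binary_dilate(mask: np.ndarray, kernel: np.ndarray, anchor) -> np.ndarray:
    h, w = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    for j in range(h):
        for i in range(w):
            for dy, dx in se_offsets(kernel, anchor):
                y, x = j - dy, i - dx
                if 0 <= y < h and 0 <= x < w and mask[y, x]:
                    out[j, i] = True
                    break
    return out


def brute_binary_erode(mask: np.ndarray, kernel: np.ndarray, anchor) -> np.ndarray:
    h, w = mask.shape
    out = np.ones_like(mask, dtype=bool)
    for j in range(h):
        for i in range(w):
            for dy, dx in se_offsets(kernel, anchor):
                y, x = j + dy, i + dx
                if 0 <= y < h and 0 <= x < w and not mask[y, x]:
                    out[j, i] = False
                    break
    return out


def _clamp(v, lo, hi):
    return max(lo, min(hi, v))


def brute_gray_dilate(img: np.ndarray, kernel: np.ndarray, anchor) -> np.ndarray:
    h, w = img.shape
    out = np.zeros_like(img)
    for j in range(h):
        for i in range(w):
            best = -np.inf
            for dy, dx in se_offsets(kernel, anchor):
                y, x = _clamp(j - dy, 0, h - 1), _clamp(i - dx, 0, w - 1)
                best = max(best, float(img[y, x]))
            out[j, i] = int(min(max(best, 0), 255))
    return out


def brute_gray_erode(img: np.ndarray, kernel: np.ndarray, anchor) -> np.ndarray:
    h, w = img.shape
    out = np.zeros_like(img)
    for j in range(h):
        for i in range(w):
            best = np.inf
            for dy, dx in se_offsets(kernel, anchor):
                y, x = _clamp(j + dy, 0, h - 1), _clamp(i + dx, 0, w - 1)
                best = min(best, float(img[y, x]))
            out[j, i] = int(min(max(best, 0), 255))
    return out


def brute_closing(img, kernel, anchor):
    return brute_gray_erode(brute_gray_dilate(img, kernel, anchor), kernel, anchor)


def brute_opening(img, kernel, anchor):
    return brute_gray_dilate(brute_gray_erode(img, kernel, anchor), kernel, anchor)


def brute_blackhat(img, kernel, anchor):
    return np.maximum(brute_closing(img, kernel, anchor).astype(int) - img.astype(int), 0).astype(np.uint8)


def brute_otsu(img: np.ndarray) -> int:
    """Smallest t maximizing between-class variance, by trying all 256."""
    values = img.ravel()
    n = values.size
    best_t, best_var = 0, -1.0
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / n, hi.size / n
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    if best_var < 0:  # constant image
        return int(values[0])
    return best_t


def brute_mean_filter(img: np.ndarray, size: int) -> np.ndarray:
    """Sliding-window mean with replicate borders, real-valued."""
    h, w = img.shape
    half = size // 2
    out = np.zeros((h, w), dtype=np.float64)
    for j in range(h):
        for i in range(w):
            acc = 0.0
            for dy in range(-half, half + 1):
                for dx in range(-half, half + 1):
                    y = _clamp(j + dy, 0, h - 1)
                    x = _clamp(i + dx, 0, w - 1)
                    acc += float(img[y, x])
            out[j, i] = acc / (size * size)
    return out


def brute_median_filter(img: np.ndarray, size: int) -> np.ndarray:
    h, w = img.shape
    half = size // 2
    out = np.zeros_like(img)
    for j in range(h):
        for i in range(w):
            vals = []
            for dy in range(-half, half + 1):
                for dx in range(-half, half + 1):
                    y = _clamp(j + dy, 0, h - 1)
                    x = _clamp(i + dx, 0, w - 1)
                    vals.append(img[y, x])
            out[j, i] = int(np.median(sorted(vals)))
    return out
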