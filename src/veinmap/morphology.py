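"""Binary and grayscale morphological primitives.

Conventions
-----------
A structuring element (SE) is a small boolean kernel with an anchor cell
and, optionally, additive gray offsets for non-flat grayscale morphology
(all zero by default).  With offsets ``s`` measured from the anchor:

* dilation samples the input at ``p - s`` (max / union),
* erosion samples the input at ``p + s`` (min / intersection),

which makes the pair an adjunction, so ``erode(dilate(.))`` is a proper
closing and ``dilate(erode(.))`` a proper opening.

Border rule: grayscale operators use replicate-edge padding; binary
dilation treats out-of-bounds input as False and binary erosion treats it
as True (so image borders do not spuriously erode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_core import as_gray, as_mask, from_wide

__all__ = [
    "StructuringElement",
    "cross3",
    "square3",
    "binary_dilate",
    "binary_erode",
    "gray_dilate",
    "gray_erode",
    "closing",
    "opening",
    "blackhat",
]


@dataclass(frozen=True, eq=False)
class StructuringElement:
    """Boolean kernel + anchor (+ optional additive gray offsets)."""

    kernel: np.ndarray
    anchor: tuple[int, int] | None = None
    values: np.ndarray | None = field(default=None)

    def __eq__(self, other):
        if not isinstance(other, StructuringElement):
            return NotImplemented
        if self.anchor != other.anchor or not np.array_equal(self.kernel, other.kernel):
            return False
        if (self.values is None) != (other.values is None):
            return False
        return self.values is None or np.array_equal(self.values, other.values)

    def __hash__(self):
        return hash((self.kernel.tobytes(), self.anchor))

    def __post_init__(self):
        kernel = np.asarray(self.kernel, dtype=bool)
        if kernel.ndim != 2 or not kernel.any():
            raise ValueError("structuring element needs a 2-D kernel with at least one true cell")
        anchor = self.anchor
        if anchor is None:
            anchor = (kernel.shape[0] // 2, kernel.shape[1] // 2)
        if not (0 <= anchor[0] < kernel.shape[0] and 0 <= anchor[1] < kernel.shape[1]):
            raise ValueError(f"anchor {anchor} outside kernel of shape {kernel.shape}")
        values = self.values
        if values is not None:
            values = np.asarray(values, dtype=np.float64)
            if values.shape != kernel.shape:
                raise ValueError("values grid must match kernel shape")
        object.__setattr__(self, "kernel", kernel)
        object.__setattr__(self, "anchor", tuple(anchor))
        object.__setattr__(self, "values", values)

    def offsets(self) -> list[tuple[int, int, float]]:
        """(dy, dx, gray offset) for every true cell, relative to the anchor."""
        ar, ac = self.anchor
        out = []
        for r, c in zip(*np.nonzero(self.kernel)):
            k = 0.0 if self.values is None else float(self.values[r, c])
            out.append((int(r) - ar, int(c) - ac, k))
        return out

    def reflected(self) -> "StructuringElement":
        """The SE reflected through its anchor."""
        k = self.kernel[::-1, ::-1]
        v = None if self.values is None else self.values[::-1, ::-1]
        h, w = self.kernel.shape
        ar, ac = self.anchor
        return StructuringElement(k, (h - 1 - ar, w - 1 - ac), v)

    @classmethod
    def from_config(cls, spec) -> "StructuringElement":
        """Build from a config value: ``"cross3"``, ``"square3"`` or a 0/1 matrix."""
        if isinstance(spec, StructuringElement):
            return spec
        if isinstance(spec, str):
            try:
                return {"cross3": cross3, "square3": square3}[spec]()
            except KeyError:
                raise ValueError(f"unknown structuring element name {spec!r}") from None
        return cls(np.asarray(spec))


def cross3() -> StructuringElement:
    """The default 3x3 cross (4-neighbourhood plus centre)."""
    return StructuringElement(np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool))


def square3() -> StructuringElement:
    return StructuringElement(np.ones((3, 3), dtype=bool))


def _shifted_view(padded: np.ndarray, dy: int, dx: int, shape: tuple[int, int], pad: tuple[int, int]):
    """View of the padded array shifted by (dy, dx), cropped to *shape*."""
    h, w = shape
    pr, pc = pad
    return padded[pr + dy : pr + dy + h, pc + dx : pc + dx + w]


def _pad_amounts(se: StructuringElement) -> tuple[int, int]:
    offs = se.offsets()
    return max(abs(o[0]) for o in offs), max(abs(o[1]) for o in offs)


def binary_dilate(mask: np.ndarray, se: StructuringElement, iterations: int = 1) -> np.ndarray:
    """Minkowski-sum dilation of a boolean mask."""
    mask = as_mask(mask)
    pr, pc = _pad_amounts(se)
    for _ in range(iterations):
        padded = np.pad(mask, ((pr, pr), (pc, pc)), constant_values=False)
        out = np.zeros_like(mask)
        for dy, dx, _ in se.offsets():
            out |= _shifted_view(padded, -dy, -dx, mask.shape, (pr, pc))
        mask = out
    return mask


def binary_erode(mask: np.ndarray, se: StructuringElement, iterations: int = 1) -> np.ndarray:
    """Erosion of a boolean mask; out-of-bounds counts as foreground."""
    mask = as_mask(mask)
    pr, pc = _pad_amounts(se)
    for _ in range(iterations):
        padded = np.pad(mask, ((pr, pr), (pc, pc)), constant_values=True)
        out = np.ones_like(mask)
        for dy, dx, _ in se.offsets():
            out &= _shifted_view(padded, dy, dx, mask.shape, (pr, pc))
        mask = out
    return mask


def _gray_op(img: np.ndarray, se: StructuringElement, minimum: bool) -> np.ndarray:
    img = as_gray(img)
    pr, pc = _pad_amounts(se)
    padded = np.pad(img.astype(np.float64), ((pr, pr), (pc, pc)), mode="edge")
    acc = None
    for dy, dx, k in se.offsets():
        if minimum:
            term = _shifted_view(padded, dy, dx, img.shape, (pr, pc)) - k
            acc = term.copy() if acc is None else np.minimum(acc, term)
        else:
            term = _shifted_view(padded, -dy, -dx, img.shape, (pr, pc)) + k
            acc = term.copy() if acc is None else np.maximum(acc, term)
    return from_wide(acc)


def gray_dilate(img: np.ndarray, se: StructuringElement, iterations: int = 1) -> np.ndarray:
    """Grayscale dilation: max over the SE support of ``I(p - s) + k(s)``."""
    for _ in range(iterations):
        img = _gray_op(img, se, minimum=False)
    return as_gray(img)


def gray_erode(img: np.ndarray, se: StructuringElement, iterations: int = 1) -> np.ndarray:
    """Grayscale erosion: min over the SE support of ``I(p + s) - k(s)``."""
    for _ in range(iterations):
        img = _gray_op(img, se, minimum=True)
    return as_gray(img)


def closing(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    return gray_erode(gray_dilate(img, se), se)


def opening(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    return gray_dilate(gray_erode(img, se), se)


def blackhat(img: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Closing minus the image; responds to dark structures thinner than the SE."""
    img = as_gray(img)
    diff = closing(img, se).astype(np.int16) - img.astype(np.int16)
    return from_wide(np.maximum(diff, 0).astype(np.float64))
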