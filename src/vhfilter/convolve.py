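"""Single-stride 3x3 convolution with explicit border and rounding contracts.

All arithmetic on the weighted sums is exact integer arithmetic; the
division by the kernel divisor is the only rounding point, and its mode is
part of the contract.  The VHT kernel is symmetric under 180-degree
rotation, so correlation and true convolution coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import clip_u8, ensure_gray
from .kernel import Kernel3x3

ROUNDING_MODES = ("floor", "half_up", "ceil")
BORDER_MODES = ("replicate", "reflect", "zero")

_PAD_MODE = {"replicate": "edge", "reflect": "reflect", "zero": "constant"}


@dataclass(frozen=True)
class FilterConfig:
    """Rounding, border, and clipping policy for :func:`filter_image`."""

    rounding: str = "half_up"
    border: str = "replicate"
    clip: bool = True

    def __post_init__(self) -> None:
        if self.rounding not in ROUNDING_MODES:
            raise ValueError(f"rounding must be one of {ROUNDING_MODES}, got {self.rounding!r}")
        if self.border not in BORDER_MODES:
            raise ValueError(f"border must be one of {BORDER_MODES}, got {self.border!r}")


def _int_divide(s: np.ndarray, d: int, rounding: str) -> np.ndarray:
    """Exact integer division of s/d under the given rounding mode."""
    if rounding == "floor":
        return s // d
    if rounding == "ceil":
        return -((-s) // d)
    if rounding == "half_up":
        # floor(s/d + 1/2) in pure integer arithmetic
        return (2 * s + d) // (2 * d)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def patch_response(patch: np.ndarray, kernel: Kernel3x3, rounding: str = "half_up") -> int:
    """Response of the kernel on a single 3x3 patch, clipped to [0, 255]."""
    patch = np.asarray(patch)
    if patch.shape != (3, 3):
        raise ValueError(f"patch must be 3x3, got shape {patch.shape}")
    if rounding not in ROUNDING_MODES:
        raise ValueError(f"rounding must be one of {ROUNDING_MODES}, got {rounding!r}")
    s = int(np.sum(kernel.weights * patch.astype(np.int64)))
    v = int(_int_divide(np.int64(s), kernel.divisor, rounding))
    return max(0, min(255, v))


def filter_image(
    img: np.ndarray, kernel: Kernel3x3, config: FilterConfig | None = None
) -> np.ndarray:
    """Apply a 3x3 kernel over a grayscale image with stride 1.

    Output has the same shape as the input; border pixels see a
    neighbourhood padded according to ``config.border``.  Every interior
    pixel equals :func:`patch_response` on its 3x3 neighbourhood.
    """
    config = config or FilterConfig()
    img = ensure_gray(img, min_size=3)
    padded = np.pad(img.astype(np.int64), 1, mode=_PAD_MODE[config.border])
    h, w = img.shape
    acc = np.zeros((h, w), dtype=np.int64)
    weights = kernel.weights
    for di in range(3):
        for dj in range(3):
            wgt = int(weights[di, dj])
            if wgt:
                acc += wgt * padded[di : di + h, dj : dj + w]
    out = _int_divide(acc, kernel.divisor, config.rounding)
    if config.clip:
        return clip_u8(out)
    return out
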