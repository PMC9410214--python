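"""Shared numeric helpers."""

from __future__ import annotations

import numpy as np


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round with ties going up (0.5 -> 1), unlike numpy's banker's rounding."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def clip_u8(x: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and cast to uint8."""
    return np.clip(x, 0, 255).astype(np.uint8)


def ensure_gray(img: np.ndarray, min_size: int = 1) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.shape[0] < min_size or img.shape[1] < min_size:
        raise ValueError(f"image {img.shape} smaller than minimum {min_size}x{min_size}")
    return img


def ensure_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"RGB image must be at least 3x3, got {img.shape[:2]}")
    return img
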