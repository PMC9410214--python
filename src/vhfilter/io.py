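"""8-bit image reading/writing for PNG, TIFF, and BMP via Pillow."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

SUPPORTED_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as uint8, RGB (HxWx3) or grayscale (HxW).

    Non-8-bit inputs are linearly rescaled to [0, 255] with a warning;
    palette and RGBA images are converted to RGB.
    """
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "F"):
            arr = np.asarray(im, dtype=float)
            lo, hi = arr.min(), arr.max()
            logger.warning("non-8-bit image %s (mode %s): rescaling [%s, %s] to [0, 255]",
                           path, im.mode, lo, hi)
            arr = np.zeros_like(arr) if hi == lo else (arr - lo) * (255.0 / (hi - lo))
            return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)
        if im.mode == "L":
            return np.asarray(im, dtype=np.uint8)
        if im.mode != "RGB":
            im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write a uint8 grayscale or RGB array; format chosen by suffix."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        raise ValueError(f"expected uint8 image, got dtype {img.dtype}")
    if img.ndim == 2:
        mode = "L"
    elif img.ndim == 3 and img.shape[2] == 3:
        mode = "RGB"
    else:
        raise ValueError(f"unsupported image shape {img.shape}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img, mode=mode).save(path)
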