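"""Smear-image preprocessing: crop/resize, complement, dehazing, grayscale.

The enhancement chain mirrors bright-field smear acquisition: the image is
complemented so its bright background becomes a dark "haze-free" prior,
dehazed with a dark-channel scattering model, complemented back, and
converted to grayscale for filtering.

Dehazing inverts the scattering model ``I = J*t + A*(1 - t)``:
the per-channel atmospheric light ``A`` is estimated from the brightest
dark-channel region, the transmission ``t`` from the normalized dark
channel, and the radiance recovered as ``J = (I - A) / max(t, t_floor) + A``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from ._util import clip_u8, ensure_gray, ensure_rgb, round_half_up

#: BT.601 luma weights for grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class DehazeParams:
    """Parameters of the dark-channel dehazing step.

    patch_size
        Side of the square local patch used for the dark channel (odd, >= 3).
    gamma
        Optional post-restoration gamma correction exponent; 1.0 disables it.
    t_floor
        Lower bound on the transmission map, guarding division blow-up.
    atmos_quantile
        Fraction of pixels (by dark-channel brightness) considered when
        estimating the atmospheric light.
    """

    patch_size: int = 15
    gamma: float = 1.0
    t_floor: float = 0.1
    atmos_quantile: float = 0.001

    def __post_init__(self) -> None:
        if self.patch_size < 3 or self.patch_size % 2 == 0:
            raise ValueError(f"patch_size must be odd and >= 3, got {self.patch_size}")
        if not 0 < self.t_floor < 1:
            raise ValueError(f"t_floor must be in (0, 1), got {self.t_floor}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if not 0 < self.atmos_quantile < 1:
            raise ValueError(f"atmos_quantile must be in (0, 1), got {self.atmos_quantile}")


def crop_resize(
    img: np.ndarray,
    box: tuple[int, int, int, int] | None,
    out_h: int,
    out_w: int,
    *,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Crop ``box`` = (top, left, height, width) out of ``img`` and resize.

    ``box=None`` means the full frame.  Bilinear resampling by default,
    nearest-neighbour with ``interpolation="nearest"``.
    """
    img = ensure_rgb(img)
    h, w = img.shape[:2]
    if box is None:
        box = (0, 0, h, w)
    top, left, bh, bw = box
    if top < 0 or left < 0 or bh <= 0 or bw <= 0 or top + bh > h or left + bw > w:
        raise ValueError(f"crop box {box} outside image of shape {(h, w)}")
    if out_h < 3 or out_w < 3:
        raise ValueError(f"output dimensions must be >= 3, got {(out_h, out_w)}")
    if interpolation not in ("bilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")

    region = img[top : top + bh, left : left + bw]
    if region.shape[:2] == (out_h, out_w):
        return region.copy()
    order = 1 if interpolation == "bilinear" else 0
    out = _sk_resize(
        region.astype(float),
        (out_h, out_w),
        order=order,
        preserve_range=True,
        anti_aliasing=(order == 1 and (out_h < bh or out_w < bw)),
    )
    return clip_u8(round_half_up(out))


def complement(img: np.ndarray) -> np.ndarray:
    """Per-channel intensity inversion v -> 255 - v (an involution)."""
    img = np.asarray(img)
    if img.dtype != np.uint8:
        if img.min() < 0 or img.max() > 255:
            raise ValueError("intensities outside [0, 255]")
        img = img.astype(np.uint8)
    return (255 - img.astype(np.int16)).astype(np.uint8)


def dark_channel(img: np.ndarray, patch_size: int = 15) -> np.ndarray:
    """Patchwise minimum over the per-pixel channel minimum.

    Accepts an RGB image (uint8 or float); returns a float map of the same
    height/width.
    """
    if patch_size < 3 or patch_size % 2 == 0:
        raise ValueError(f"patch_size must be odd and >= 3, got {patch_size}")
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        per_pixel_min = img.min(axis=2)
    elif img.ndim == 2:
        per_pixel_min = img
    else:
        raise ValueError(f"expected 2-D or 3-D image, got shape {img.shape}")
    return ndimage.minimum_filter(per_pixel_min, size=patch_size, mode="nearest")


def estimate_atmospheric_light(
    img: np.ndarray, patch_size: int = 15, quantile: float = 0.001
) -> np.ndarray:
    """Per-channel atmospheric light estimate.

    Candidate pixels are the top ``quantile`` of the dark channel; among
    them the brightest tenth (by luma) is averaged per channel, the usual
    refinement that keeps the estimate on the haze-coloured background
    rather than on mid-range objects.
    """
    img = ensure_rgb(img)
    dc = dark_channel(img, patch_size)
    flat_dc = dc.ravel()
    n_candidates = max(1, int(round(flat_dc.size * quantile)))
    candidate_idx = np.argpartition(flat_dc, -n_candidates)[-n_candidates:]
    pixels = img.reshape(-1, 3)[candidate_idx].astype(float)
    luma = pixels @ np.asarray(LUMA_WEIGHTS)
    n_bright = max(1, n_candidates // 10)
    bright_idx = np.argpartition(luma, -n_bright)[-n_bright:]
    atmos = pixels[bright_idx].mean(axis=0)
    return np.maximum(atmos, 1.0)


def transmission_map(
    img: np.ndarray, atmos: np.ndarray, patch_size: int = 15
) -> np.ndarray:
    """Transmission estimate ``1 - dark_channel(I / A)``, clipped to [0, 1]."""
    img = ensure_rgb(img)
    atmos = np.asarray(atmos, dtype=float).reshape(-1)
    if atmos.shape != (3,):
        raise ValueError(f"atmos must have 3 components, got shape {atmos.shape}")
    if np.any(atmos <= 0):
        raise ValueError("atmospheric light components must be > 0")
    normalized = img.astype(float) / atmos
    return np.clip(1.0 - dark_channel(normalized, patch_size), 0.0, 1.0)


def dehaze(img: np.ndarray, params: DehazeParams | None = None) -> np.ndarray:
    """Restore a hazed RGB image via the dark-channel scattering inverse.

    Degenerate (constant) inputs are returned unchanged with a warning,
    since no atmospheric light can be estimated from them.
    """
    params = params or DehazeParams()
    img = ensure_rgb(img)
    if img.min() == img.max():
        warnings.warn("constant image: dehazing skipped", stacklevel=2)
        return img.copy()

    atmos = estimate_atmospheric_light(img, params.patch_size, params.atmos_quantile)
    t = transmission_map(img, atmos, params.patch_size)
    t = np.maximum(t, params.t_floor)[..., None]
    restored = (img.astype(float) - atmos) / t + atmos
    restored = np.clip(restored, 0.0, 255.0)
    if params.gamma != 1.0:
        restored = 255.0 * (restored / 255.0) ** params.gamma
    return clip_u8(round_half_up(restored))


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """BT.601 luminance conversion, rounded half-up to 8 bits."""
    img = ensure_rgb(img)
    y = img.astype(float) @ np.asarray(LUMA_WEIGHTS)
    return clip_u8(round_half_up(y))


def preprocess_image(
    img: np.ndarray,
    params: DehazeParams | None = None,
    *,
    via_complement: bool = True,
    grayscale: bool = True,
) -> np.ndarray:
    """Full preprocessing chain feeding the hexagonal filter.

    With ``via_complement`` (the default) the dehazing operates on the
    complemented image and the result is complemented back, so the
    dark-channel prior applies to the smear's bright background.
    """
    img = ensure_rgb(img)
    if via_complement:
        out = complement(dehaze(complement(img), params))
    else:
        out = dehaze(img, params)
    if grayscale:
        return to_grayscale(out)
    return out
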