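"""Seeded synthetic white-blood-cell smear images with known clean/hazed pairs.

The generator paints a bright stained background, an elliptical cytoplasm,
a darker multi-lobed nucleus, and a dense jittered lattice of small dark
granules/platelets.  The granules guarantee that every local patch contains
a near-zero channel minimum, which is exactly the prior the dark-channel
dehazer relies on — without them the constant-transmission haze model is
not invertible from the image alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._util import clip_u8, ensure_rgb, round_half_up


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic smear generator (all seeded)."""

    height: int = 240
    width: int = 320
    cell_radius_range: tuple[float, float] = (45.0, 65.0)
    nucleus_lobes: int = 3
    haze_t: float = 0.6
    atmos: tuple[float, float, float] = (220.0, 220.0, 220.0)
    blur_sigma: float = 0.6
    noise_sigma: float = 2.0
    seed: int = 0
    background: tuple[float, float, float] = (228.0, 212.0, 220.0)
    cytoplasm: tuple[float, float, float] = (200.0, 174.0, 208.0)
    nucleus: tuple[float, float, float] = (95.0, 60.0, 140.0)
    granules: bool = True
    granule_spacing: int = 9
    granule_radius: int = 2
    granule_value: tuple[float, float, float] = (4.0, 2.0, 8.0)

    def __post_init__(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("frame must be at least 16x16")
        lo, hi = self.cell_radius_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad cell_radius_range {self.cell_radius_range}")
        if 2 * hi >= min(self.height, self.width):
            raise ValueError(
                f"cell radius up to {hi} does not fit a {self.height}x{self.width} frame"
            )
        if not 0 < self.haze_t <= 1:
            raise ValueError(f"haze_t must be in (0, 1], got {self.haze_t}")
        if self.nucleus_lobes < 1:
            raise ValueError("nucleus_lobes must be >= 1")
        if self.blur_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("blur_sigma and noise_sigma must be >= 0")


def _disc_mask(h: int, w: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def generate_wbc_image(params: SynthParams | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Generate one clean smear image and its nucleus mask.

    Returns ``(clean, nucleus_mask)`` where ``clean`` is HxWx3 uint8 and
    ``nucleus_mask`` is a boolean HxW map.  Deterministic for a fixed seed.
    """
    params = params or SynthParams()
    rng = np.random.default_rng(params.seed)
    h, w = params.height, params.width
    img = np.empty((h, w, 3), dtype=float)
    img[:] = params.background

    # elliptical cytoplasm, jittered around the frame centre
    r_lo, r_hi = params.cell_radius_range
    ra = rng.uniform(r_lo, r_hi)
    rb = rng.uniform(r_lo, r_hi)
    max_r = max(ra, rb)
    cy = h / 2 + rng.uniform(-1, 1) * max(0.0, h / 2 - max_r - 4)
    cx = w / 2 + rng.uniform(-1, 1) * max(0.0, w / 2 - max_r - 4)
    theta = rng.uniform(0, np.pi)
    yy, xx = np.ogrid[:h, :w]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    cyto = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
    img[cyto] = params.cytoplasm

    # nucleus: overlapping discs inside the cytoplasm
    nucleus_mask = np.zeros((h, w), dtype=bool)
    lobe_r = 0.38 * min(ra, rb)
    for _ in range(params.nucleus_lobes):
        off = 0.4 * min(ra, rb)
        ly = cy + rng.uniform(-off, off)
        lx = cx + rng.uniform(-off, off)
        nucleus_mask |= _disc_mask(h, w, ly, lx, lobe_r * rng.uniform(0.8, 1.1))
    nucleus_mask &= cyto
    img[nucleus_mask] = params.nucleus

    # dense jittered granule lattice: every local patch gets a dark pixel
    if params.granules:
        sp = params.granule_spacing
        jit = max(1, sp // 3)
        for gy in range(sp // 2, h, sp):
            for gx in range(sp // 2, w, sp):
                py = int(np.clip(gy + rng.integers(-jit, jit + 1), 0, h - 1))
                px = int(np.clip(gx + rng.integers(-jit, jit + 1), 0, w - 1))
                mask = _disc_mask(h, w, py, px, params.granule_radius)
                img[mask] = params.granule_value

    if params.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(params.blur_sigma, params.blur_sigma, 0))
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    return clip_u8(round_half_up(img)), nucleus_mask


def add_haze(
    clean: np.ndarray, t: float, atmos: tuple[float, float, float] | np.ndarray
) -> np.ndarray:
    """Apply the scattering forward model ``I = clean*t + atmos*(1 - t)``."""
    if not 0 < t <= 1:
        raise ValueError(f"transmission t must be in (0, 1], got {t}")
    clean = ensure_rgb(clean)
    atmos = np.asarray(atmos, dtype=float).reshape(1, 1, 3)
    hazed = clean.astype(float) * t + atmos * (1.0 - t)
    return clip_u8(round_half_up(hazed))


def generate_pair(params: SynthParams | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convenience: (clean, hazed, nucleus_mask) with the params' own haze."""
    params = params or SynthParams()
    clean, mask = generate_wbc_image(params)
    hazed = add_haze(clean, params.haze_t, params.atmos)
    return clean, hazed, mask
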