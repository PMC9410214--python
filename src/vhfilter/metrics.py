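"""Full- and no-reference image quality metrics, plus comparator filters.

Full-reference: MSE, PSNR, MAE, NAE, NCC, SSIM.  No-reference: Shannon
entropy and the blockwise EME contrast measure.  Also provides
transform-domain alpha rooting and the three classical comparator
filters (histogram equalization, 3x3 mean, 3x3 adaptive Wiener).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.signal import wiener as _scipy_wiener
from skimage import exposure as _sk_exposure
from skimage.metrics import structural_similarity as _sk_ssim

from ._util import clip_u8, ensure_gray, round_half_up
from .convolve import FilterConfig, filter_image
from .kernel import MEAN_KERNEL

#: PSNR reported for identical images instead of infinity.
PSNR_CAP_DB = 100.0

REFERENCE_FILTERS = ("histogram_equalization", "mean3x3", "wiener3x3")


class ErrorMetrics(NamedTuple):
    mse: float
    psnr: float
    mae: float
    nae: float
    ncc: float


@dataclass(frozen=True)
class EMEConfig:
    """Block layout for the EME contrast measure.

    Either fix the number of blocks (``k1`` rows x ``k2`` columns) or leave
    them None to tile with ``block_size``-pixel blocks; trailing partial
    blocks are included either way.
    """

    k1: int | None = None
    k2: int | None = None
    block_size: int = 8
    epsilon: float = 1e-4

    def __post_init__(self) -> None:
        for k in (self.k1, self.k2):
            if k is not None and k < 1:
                raise ValueError("block counts must be >= 1")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class MetricReport:
    """Named collection of quality metrics for one (reference, test) pair."""

    mse: float
    psnr: float
    ssim: float
    ncc: float
    nae: float
    mae: float
    entropy: float
    eme: float

    def to_dict(self) -> dict[str, float]:
        return dict(vars(self))


def _check_pair(original: np.ndarray, result: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    original = ensure_gray(original)
    result = ensure_gray(result)
    if original.shape != result.shape:
        raise ValueError(f"shape mismatch: {original.shape} vs {result.shape}")
    return original.astype(float), result.astype(float)


def error_metrics(original: np.ndarray, result: np.ndarray) -> ErrorMetrics:
    """MSE, PSNR (dB, capped for identical images), MAE, NAE, NCC.

    NAE normalizes the absolute error by the reference's total intensity;
    NCC normalizes the cross term by the reference's energy.  Both are
    undefined for an all-zero reference and reported as NaN with a warning.
    """
    o, r = _check_pair(original, result)
    diff = o - r
    mse = float(np.mean(diff**2))
    mae = float(np.mean(np.abs(diff)))
    psnr = PSNR_CAP_DB if mse == 0 else float(10.0 * np.log10(255.0**2 / mse))
    psnr = min(psnr, PSNR_CAP_DB)

    sum_o = float(o.sum())
    sum_o2 = float((o**2).sum())
    if sum_o == 0:
        warnings.warn("all-zero reference: NAE and NCC undefined, reporting NaN", stacklevel=2)
        nae = ncc = float("nan")
    else:
        nae = float(np.abs(diff).sum() / sum_o)
        ncc = float((o * r).sum() / sum_o2)
    return ErrorMetrics(mse=mse, psnr=psnr, mae=mae, nae=nae, ncc=ncc)


def ssim(
    original: np.ndarray,
    result: np.ndarray,
    *,
    win_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity over Gaussian-weighted local windows.

    Standard stabilizers C1=(0.01*255)^2, C2=(0.03*255)^2.
    """
    o, r = _check_pair(original, result)
    if min(o.shape) < win_size:
        raise ValueError(f"images smaller than the {win_size}x{win_size} SSIM window")
    return float(
        _sk_ssim(
            o,
            r,
            data_range=255.0,
            gaussian_weights=True,
            sigma=sigma,
            win_size=win_size,
            use_sample_covariance=False,
        )
    )


def entropy(img: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin intensity histogram."""
    img = ensure_gray(img)
    counts = np.bincount(img.astype(np.uint8).ravel(), minlength=256)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def eme(img: np.ndarray, config: EMEConfig | None = None) -> float:
    """Blockwise contrast: mean of 20*log10((Imax + eps) / (Imin + eps))."""
    config = config or EMEConfig()
    img = ensure_gray(img).astype(float)
    h, w = img.shape
    k1 = config.k1 if config.k1 is not None else max(1, -(-h // config.block_size))
    k2 = config.k2 if config.k2 is not None else max(1, -(-w // config.block_size))
    row_edges = np.linspace(0, h, k1 + 1).round().astype(int)
    col_edges = np.linspace(0, w, k2 + 1).round().astype(int)
    eps = config.epsilon
    total = 0.0
    count = 0
    for r0, r1 in zip(row_edges[:-1], row_edges[1:]):
        if r1 <= r0:
            continue
        for c0, c1 in zip(col_edges[:-1], col_edges[1:]):
            if c1 <= c0:
                continue
            block = img[r0:r1, c0:c1]
            total += 20.0 * np.log10((block.max() + eps) / (block.min() + eps))
            count += 1
    return total / count


def alpha_rooting(img: np.ndarray, alpha: float) -> np.ndarray:
    """Fourier-domain alpha rooting with DC-relative magnitude scaling.

    Spectral magnitudes are raised to the power ``alpha`` relative to the
    DC magnitude, so the image mean is preserved and ``alpha = 1`` is the
    identity.  The real part is mapped back to [0, 255] (min-max rescale
    only when it leaves the range).
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    img = ensure_gray(img)
    f = np.fft.fft2(img.astype(float))
    mag = np.abs(f)
    dc = mag[0, 0] if mag[0, 0] > 0 else mag.max()
    if dc == 0:
        return img.astype(np.uint8).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(mag > 0, (mag / dc) ** (alpha - 1.0), 0.0)
    out = np.fft.ifft2(f * gain).real
    lo, hi = out.min(), out.max()
    # half-level tolerance so float round-off never triggers a rescale
    if lo < -0.5 or hi > 255.5:
        if hi > lo:
            out = (out - lo) * (255.0 / (hi - lo))
        else:
            out = np.full_like(out, np.clip(lo, 0, 255))
    return clip_u8(round_half_up(out))


def apply_reference_filter(img: np.ndarray, name: str) -> np.ndarray:
    """One of the classical comparator filters.

    ``histogram_equalization``: global 256-bin equalization.
    ``mean3x3``: 3x3 box average (replicate border, half-up rounding).
    ``wiener3x3``: locally adaptive Wiener filter on 3x3 neighbourhoods.
    """
    img = ensure_gray(img, min_size=3).astype(np.uint8)
    if name == "histogram_equalization":
        out = _sk_exposure.equalize_hist(img, nbins=256) * 255.0
        return clip_u8(round_half_up(out))
    if name == "mean3x3":
        return filter_image(img, MEAN_KERNEL, FilterConfig(rounding="half_up"))
    if name == "wiener3x3":
        # replicate-pad so border statistics are not biased by zero padding
        padded = np.pad(img.astype(float), 1, mode="edge")
        with np.errstate(divide="ignore", invalid="ignore"):
            out = _scipy_wiener(padded, (3, 3))[1:-1, 1:-1]
        bad = ~np.isfinite(out)
        if bad.any():  # zero local variance makes scipy's estimate 0/0
            out[bad] = img.astype(float)[bad]
        return clip_u8(round_half_up(out))
    raise ValueError(f"unknown reference filter {name!r}; expected one of {REFERENCE_FILTERS}")


def full_report(
    original: np.ndarray,
    result: np.ndarray,
    eme_config: EMEConfig | None = None,
) -> MetricReport:
    """All metrics for a (reference, test) pair; entropy/EME are of the test."""
    em = error_metrics(original, result)
    return MetricReport(
        mse=em.mse,
        psnr=em.psnr,
        ssim=ssim(original, result),
        ncc=em.ncc,
        nae=em.nae,
        mae=em.mae,
        entropy=entropy(result),
        eme=eme(result, eme_config),
    )
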