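"""Evaluation drivers: CFF sweep, method comparison, alpha sweep.

Each driver returns a pandas DataFrame so the CLI can write it as CSV
unchanged.  The sweep compares each filtered output against the pre-filter
image — the only reference that exists in the protocol.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import ensure_gray
from .convolve import FilterConfig, filter_image
from .kernel import CFF_UNIT_GAIN, derive_kernel
from .metrics import (
    EMEConfig,
    alpha_rooting,
    apply_reference_filter,
    eme,
    entropy,
    error_metrics,
    ssim,
)

COMPARE_METHODS = ("vhf", "he", "mean", "wiener")

_REFERENCE_NAME = {
    "he": "histogram_equalization",
    "mean": "mean3x3",
    "wiener": "wiener3x3",
}


def sweep_cff(
    original: np.ndarray,
    cff_range: Iterable[int] = range(7, 20),
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """PSNR/MSE of the VHT filter against the input, for each CFF value."""
    original = ensure_gray(original, min_size=3)
    cffs = list(cff_range)
    if not cffs:
        raise ValueError("cff_range must be nonempty")
    rows = []
    for cff in cffs:
        filtered = filter_image(original, derive_kernel(cff), config)
        em = error_metrics(original, filtered)
        rows.append({"cff": int(cff), "psnr": em.psnr, "mse": em.mse})
    return pd.DataFrame(rows)


def _apply_method(img: np.ndarray, method: str, cff: int, config: FilterConfig | None) -> np.ndarray:
    if method == "vhf":
        return filter_image(img, derive_kernel(cff), config)
    if method in _REFERENCE_NAME:
        return apply_reference_filter(img, _REFERENCE_NAME[method])
    raise ValueError(f"unknown method {method!r}; expected one of {COMPARE_METHODS}")


def compare_methods(
    original: np.ndarray,
    methods: Sequence[str] = COMPARE_METHODS,
    *,
    cff: int = CFF_UNIT_GAIN,
    config: FilterConfig | None = None,
    eme_config: EMEConfig | None = None,
) -> pd.DataFrame:
    """Per-method metric table (PSNR, MSE, SSIM, entropy, NAE, NCC)."""
    original = ensure_gray(original, min_size=11)
    if not methods:
        raise ValueError("methods must be nonempty")
    rows = []
    for method in methods:
        out = _apply_method(original, method, cff, config)
        em = error_metrics(original, out)
        rows.append(
            {
                "method": method,
                "psnr": em.psnr,
                "mse": em.mse,
                "ssim": ssim(original, out),
                "entropy": entropy(out),
                "nae": em.nae,
                "ncc": em.ncc,
            }
        )
    return pd.DataFrame(rows)


def compare_methods_batch(
    originals: Sequence[np.ndarray],
    methods: Sequence[str] = COMPARE_METHODS,
    **kwargs,
) -> pd.DataFrame:
    """Batch comparison: one row per (image, method) plus per-method means."""
    if not len(originals):
        raise ValueError("need at least one image")
    frames = []
    for i, img in enumerate(originals):
        df = compare_methods(img, methods, **kwargs)
        df.insert(0, "image", i)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    means = table.groupby("method", sort=False).mean(numeric_only=True).reset_index()
    means["image"] = "mean"
    return pd.concat([table, means], ignore_index=True)


def alpha_sweep(
    original: np.ndarray,
    noisy: np.ndarray,
    alphas: Sequence[float],
    eme_config: EMEConfig | None = None,
) -> pd.DataFrame:
    """EME of alpha-rooted versions of a clean and a degraded image."""
    if not len(alphas):
        raise ValueError("alphas must be nonempty")
    if any(a <= 0 for a in alphas):
        raise ValueError("all alpha values must be > 0")
    original = ensure_gray(original)
    noisy = ensure_gray(noisy)
    rows = []
    for a in alphas:
        rows.append(
            {
                "alpha": float(a),
                "eme_original": eme(alpha_rooting(original, a), eme_config),
                "eme_noisy": eme(alpha_rooting(noisy, a), eme_config),
            }
        )
    return pd.DataFrame(rows)
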