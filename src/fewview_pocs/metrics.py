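"""Image-quality metrics: SSIM, PSNR and SNR, plus a small report table.

PSNR uses an explicit peak value: ``10 log10(peak^2 / MSE)``.  SNR is the
reference-power form ``10 log10(mean(ref^2) / MSE)``; with a fixed reference
and peak this makes ``PSNR - SNR = 10 log10(peak^2 / mean(ref^2))`` a
constant independent of the image under test, which is the behavior the
two metrics should exhibit when tabulated across reconstruction methods.
SSIM is the standard mean local structural-similarity index (Gaussian
window, sigma 1.5, K1 = 0.01, K2 = 0.03).

The default peak / data range is 1.59, the upper end of the display window
used for the disc phantom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .geometry import Image2D

__all__ = [
    "DEFAULT_PEAK",
    "MetricsReport",
    "compute_psnr",
    "compute_snr",
    "compute_ssim",
    "evaluate",
    "format_table",
]

DEFAULT_PEAK = 1.59


def _as_array(img: Image2D | np.ndarray) -> np.ndarray:
    return img.data if isinstance(img, Image2D) else np.asarray(img, dtype=float)


def _check_shapes(test: np.ndarray, reference: np.ndarray) -> None:
    if test.shape != reference.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {reference.shape}")


def compute_psnr(
    test: Image2D | np.ndarray, reference: Image2D | np.ndarray,
    peak: float = DEFAULT_PEAK,
) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    if peak <= 0:
        raise ValueError("peak must be > 0")
    t, r = _as_array(test), _as_array(reference)
    _check_shapes(t, r)
    mse = float(np.mean((t - r) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def compute_snr(test: Image2D | np.ndarray, reference: Image2D | np.ndarray) -> float:
    """Reference-power signal-to-noise ratio in dB; ``inf`` for identical images."""
    t, r = _as_array(test), _as_array(reference)
    _check_shapes(t, r)
    power = float(np.mean(r**2))
    if power == 0.0:
        raise ValueError("reference image is identically zero")
    mse = float(np.mean((t - r) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(power / mse)


def compute_ssim(
    test: Image2D | np.ndarray, reference: Image2D | np.ndarray,
    data_range: float = DEFAULT_PEAK,
) -> float:
    """Mean local SSIM with Gaussian weighting (sigma 1.5)."""
    t, r = _as_array(test), _as_array(reference)
    _check_shapes(t, r)
    return float(
        structural_similarity(
            r, t, data_range=data_range, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=0.01, K2=0.03,
        )
    )


@dataclass(frozen=True)
class MetricsReport:
    method_label: str
    ssim: float
    psnr: float
    snr: float
    peak_value: float


def evaluate(
    test: Image2D | np.ndarray, reference: Image2D | np.ndarray,
    label: str, peak: float = DEFAULT_PEAK,
) -> MetricsReport:
    """All three metrics of a reconstruction against the ground truth."""
    return MetricsReport(
        method_label=label,
        ssim=compute_ssim(test, reference, data_range=peak),
        psnr=compute_psnr(test, reference, peak=peak),
        snr=compute_snr(test, reference),
        peak_value=peak,
    )


def _fmt(v: float) -> str:
    return "inf" if np.isinf(v) else f"{v:.4f}"


def format_table(reports: list[MetricsReport], sep: str = "\t") -> str:
    """Delimited table, one method per row: SSIM, PSNR (dB), SNR (dB)."""
    lines = [sep.join(["Method", "SSIM", "PSNR", "SNR"])]
    for r in reports:
        lines.append(sep.join([r.method_label, _fmt(r.ssim), _fmt(r.psnr), _fmt(r.snr)]))
    return "\n".join(lines)
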