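"""Image-quality metrics: PSNR on unit-range images and SSIM.

PSNR is defined on images scaled to [0, 1] as −10·log10(MSE) (the peak
term is 1 so it drops out).  SSIM is available in two modes:

* ``global`` — a single luminance/contrast/structure statistic computed
  from whole-image means, standard deviations and covariance;
* ``windowed`` — the canonical sliding-window algorithm (uniform 7×7
  windows, sample-covariance normalization), averaged over the valid
  region.

For reconstructions, amplitude images are min-max normalized before
comparison and phase images are affinely aligned to the reference (a
global phase offset/scale is unidentifiable in FPM).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .exceptions import DimensionMismatchError, ValidationError

__all__ = ["MetricReport", "psnr", "mse", "ssim", "normalize_unit", "compare_images", "compare_complex"]


@dataclass(frozen=True)
class MetricReport:
    psnr_db: float
    ssim: float
    mse: float


def mse(reference: np.ndarray, test: np.ndarray) -> float:
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise DimensionMismatchError(
            f"shapes {reference.shape} and {test.shape} differ"
        )
    return float(np.mean((reference - test) ** 2))


def psnr(reference: np.ndarray, test: np.ndarray, warn_range: bool = True) -> float:
    """Peak signal-to-noise ratio in dB for unit-range images.

    Identical images give ``+inf``.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if warn_range:
        for name, img in (("reference", reference), ("test", test)):
            if img.min() < -1e-9 or img.max() > 1 + 1e-9:
                warnings.warn(
                    f"{name} image outside [0, 1] (range [{img.min():.3g}, "
                    f"{img.max():.3g}]); PSNR assumes unit dynamic range",
                    stacklevel=2,
                )
    err = mse(reference, test)
    if err == 0:
        return float("inf")
    return float(-10.0 * np.log10(err))


def _global_ssim(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    mu1, mu2 = x.mean(), y.mean()
    s1, s2 = x.std(), y.std()
    s12 = float(np.mean((x - mu1) * (y - mu2)))
    lum_con = (2 * mu1 * mu2 + c1) / (mu1**2 + mu2**2 + c1)
    struct = (2 * s12 + c2) / (s1**2 + s2**2 + c2)
    return float(lum_con * struct)


def _windowed_ssim(x: np.ndarray, y: np.ndarray, c1: float, c2: float, win: int) -> float:
    if win % 2 == 0 or win < 3:
        raise ValidationError("window size must be an odd integer >= 3")
    ns = win * win
    cov_norm = ns / (ns - 1)  # sample statistics
    ux = uniform_filter(x, win)
    uy = uniform_filter(y, win)
    uxx = uniform_filter(x * x, win)
    uyy = uniform_filter(y * y, win)
    uxy = uniform_filter(x * y, win)
    vx = cov_norm * (uxx - ux * ux)
    vy = cov_norm * (uyy - uy * uy)
    vxy = cov_norm * (uxy - ux * uy)
    s_map = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    pad = (win - 1) // 2
    return float(s_map[pad:-pad, pad:-pad].mean())


def ssim(
    reference: np.ndarray,
    test: np.ndarray,
    c1: float = 1e-4,
    c2: float = 9e-4,
    mode: str = "windowed",
    win_size: int = 7,
) -> float:
    """Structural similarity on unit-range images; result in [−1, 1].

    Defaults C1 = (0.01·L)², C2 = (0.03·L)² with L = 1.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape:
        raise DimensionMismatchError("SSIM inputs must share a shape")
    if c1 <= 0 or c2 <= 0:
        raise ValidationError("stabilizing constants must be positive")
    if mode == "global":
        return _global_ssim(reference, test, c1, c2)
    if mode == "windowed":
        return _windowed_ssim(reference, test, c1, c2, win_size)
    raise ValidationError(f"unknown SSIM mode {mode!r}")


def normalize_unit(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant images map to zeros."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def compare_images(
    reference: np.ndarray, test: np.ndarray, mode: str = "windowed"
) -> MetricReport:
    ref = np.asarray(reference, float)
    tst = np.asarray(test, float)
    return MetricReport(
        psnr_db=psnr(ref, tst, warn_range=False),
        ssim=ssim(ref, tst, mode=mode),
        mse=mse(ref, tst),
    )


def _affine_align(test: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares fit a·test + b to the reference."""
    t = test.ravel()
    A = np.column_stack([t, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(A, reference.ravel(), rcond=None)
    return (coef[0] * test + coef[1]).reshape(reference.shape)


def compare_complex(
    reference_values: np.ndarray,
    test_values: np.ndarray,
    mode: str = "windowed",
) -> dict[str, float]:
    """Amplitude/phase comparison protocol for complex reconstructions.

    Amplitudes are min-max normalized to [0, 1] independently; phases are
    affinely aligned to the reference (global offset and sign are
    unidentifiable) and both mapped to [0, 1] by the reference range.
    Returns psnr_amp, ssim_amp, psnr_phase, ssim_phase.
    """
    ref_amp = normalize_unit(np.abs(reference_values))
    tst_amp = normalize_unit(np.abs(test_values))
    amp = compare_images(ref_amp, tst_amp, mode)

    ref_ph = np.angle(np.asarray(reference_values, complex))
    tst_ph = _affine_align(np.angle(np.asarray(test_values, complex)), ref_ph)
    lo, hi = ref_ph.min(), ref_ph.max()
    span = (hi - lo) if hi > lo else 1.0
    ref_u = (ref_ph - lo) / span
    tst_u = np.clip((tst_ph - lo) / span, 0.0, 1.0)
    ph = compare_images(ref_u, tst_u, mode)
    return {
        "psnr_amp": amp.psnr_db,
        "ssim_amp": amp.ssim,
        "psnr_phase": ph.psnr_db,
        "ssim_phase": ph.ssim,
    }
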