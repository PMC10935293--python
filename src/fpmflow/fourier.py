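"""Centered, unitary 2-D Fourier transforms and pupil-window indexing.

Conventions used throughout the package:

* arrays are stored with pixel (0, 0) at the top-left;
* frequency-domain arrays use the *centered* layout: the zero-frequency
  sample sits at index ``(n // 2, n // 2)``;
* all transforms are unitary (``norm="ortho"``), so Parseval's identity
  holds exactly and adjoints of the FFT are inverse FFTs.

Cropping the central ``m x m`` window of an ``M x M`` spectrum and applying
the inverse transform implements Fourier-domain decimation; the factor
``sqrt(m*m / (M*M))`` (:func:`decimation_scale`) makes it value-preserving,
i.e. a constant field of amplitude 1 decimates to amplitude 1.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "decimation_scale",
    "window_bounds",
    "crop_window",
    "embed_window",
    "pad_spectrum",
    "fourier_upsample",
]

_AXES = (-2, -1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary 2-D FFT between centered space and centered frequency layouts."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), norm="ortho", axes=_AXES),
        axes=_AXES,
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Unitary 2-D inverse FFT, inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=_AXES), norm="ortho", axes=_AXES),
        axes=_AXES,
    )


def decimation_scale(hires_shape: tuple[int, int], lores_shape: tuple[int, int]) -> float:
    """Amplitude factor making Fourier-window decimation value-preserving."""
    mr, mc = lores_shape
    Mr, Mc = hires_shape
    return float(np.sqrt((mr * mc) / (Mr * Mc)))


def window_bounds(
    grid_shape: tuple[int, int],
    window_shape: tuple[int, int],
    shift: tuple[int, int] = (0, 0),
) -> tuple[slice, slice]:
    """Slices of a ``window_shape`` window centered ``shift`` pixels away
    from the zero-frequency pixel of a centered ``grid_shape`` grid.

    Raises ``ValueError`` if the window leaves the grid; callers translate
    this into :class:`~fpmflow.exceptions.OutOfBandError` with context.
    """
    out = []
    for size, win, s in zip(grid_shape, window_shape, shift):
        c = size // 2 + int(s)
        lo = c - win // 2
        hi = lo + win
        if lo < 0 or hi > size:
            raise ValueError(
                f"window of size {win} centered at pixel {c} leaves grid of size {size}"
            )
        out.append(slice(lo, hi))
    return out[0], out[1]


def crop_window(
    arr: np.ndarray, window_shape: tuple[int, int], shift: tuple[int, int] = (0, 0)
) -> np.ndarray:
    sr, sc = window_bounds(arr.shape[-2:], window_shape, shift)
    return arr[..., sr, sc]


def embed_window(
    arr: np.ndarray,
    grid_shape: tuple[int, int],
    shift: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Zero-pad ``arr`` into a larger centered grid at the given shift."""
    out = np.zeros(arr.shape[:-2] + tuple(grid_shape), dtype=arr.dtype)
    sr, sc = window_bounds(grid_shape, arr.shape[-2:], shift)
    out[..., sr, sc] = arr
    return out


def pad_spectrum(spectrum: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    return embed_window(spectrum, target_shape)


def fourier_upsample(field: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Sinc-interpolate a (possibly complex) field onto a finer grid.

    Value-preserving: a constant field keeps its value.
    """
    small = np.asarray(field)
    spec = fft2c(small.astype(complex))
    big = ifft2c(pad_spectrum(spec, target_shape))
    return big / decimation_scale(target_shape, small.shape[-2:])
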