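"""FPM forward imaging: shifted spectrum → pupil low-pass → intensity.

Under oblique illumination with transverse frequency ``k_n`` the object
spectrum appears shifted, ``O(k − k_n)``; the objective transmits only the
pupil disk around zero frequency, so the camera field is the inverse
transform of the pupil-windowed shifted spectrum and the camera records its
squared modulus.  Detector downsampling is implemented as Fourier-domain
decimation: the pupil window is the central ``m × m`` crop of the high-res
spectrum (``m = M / u``), which is the standard FPM forward model.

LED frequencies are quantized to the nearest integer pixel of the high-res
frequency grid so that reconstruction write-backs operate on aligned
windows; the sub-pixel residual is recorded for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionMismatchError, OutOfBandError, ValidationError
from .fourier import crop_window, decimation_scale, fft2c, ifft2c, pad_spectrum
from .optics import LEDArray, OpticalSystem, Pupil

__all__ = [
    "ComplexField",
    "NoiseSpec",
    "AcquisitionStack",
    "quantize_shift",
    "shift_spectrum",
    "forward_image",
    "simulate_dataset",
    "upsample_intensity",
]


@dataclass
class ComplexField:
    """A 2-D complex amplitude in either the space or frequency domain.

    ``sampling`` is the pixel pitch in µm (space domain) or cycles/µm
    (frequency domain).
    """

    values: np.ndarray
    domain: str = "space"  # "space" | "frequency"
    sampling: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if self.domain not in ("space", "frequency"):
            raise ValidationError(f"unknown domain {self.domain!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def real(self) -> np.ndarray:
        return self.values.real

    @property
    def imag(self) -> np.ndarray:
        return self.values.imag

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def to_frequency(self) -> "ComplexField":
        if self.domain == "frequency":
            return self
        n = self.shape[0]
        return ComplexField(fft2c(self.values), "frequency", 1.0 / (n * self.sampling))

    def to_space(self) -> "ComplexField":
        if self.domain == "space":
            return self
        n = self.shape[0]
        return ComplexField(ifft2c(self.values), "space", 1.0 / (n * self.sampling))


@dataclass(frozen=True)
class NoiseSpec:
    """Optional detector noise: Poisson shot noise at a photon budget
    (mean photons per unit intensity) plus additive Gaussian read noise.
    Both default off, matching noiseless simulation."""

    photon_budget: float | None = None
    read_noise_std: float = 0.0

    @property
    def enabled(self) -> bool:
        return self.photon_budget is not None or self.read_noise_std > 0

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image
        if self.photon_budget is not None:
            if self.photon_budget <= 0:
                raise ValidationError("photon budget must be positive")
            out = rng.poisson(np.clip(out, 0, None) * self.photon_budget) / self.photon_budget
        if self.read_noise_std > 0:
            out = out + rng.normal(0.0, self.read_noise_std, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass
class AcquisitionStack:
    """Low-resolution intensity images paired with illumination wavevectors.

    ``images[i]`` was captured under illumination ``wavevectors[i]``
    (cycles/µm); order follows the LED scan order.
    """

    images: np.ndarray  # (N, m, m) non-negative
    wavevectors: np.ndarray  # (N, 2) as (kx, ky)
    system: OpticalSystem
    leds: LEDArray | None = None
    noise_seed: int | None = None
    shift_residuals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.wavevectors = np.asarray(self.wavevectors, dtype=float)
        if len(self.images) != len(self.wavevectors):
            raise DimensionMismatchError(
                f"{len(self.images)} images but {len(self.wavevectors)} wavevectors"
            )
        if np.any(self.images < 0):
            raise ValidationError("intensity images must be non-negative")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def center_index(self) -> int:
        return int(np.argmin(np.hypot(*self.wavevectors.T)))


# ---------------------------------------------------------------------------
# forward operations
# ---------------------------------------------------------------------------


def quantize_shift(k_n, system: OpticalSystem) -> tuple[tuple[int, int], tuple[float, float]]:
    """Integer pixel shift (rows, cols) nearest to k_n plus the residual.

    ``k_n = (k_x, k_y)``; columns move with k_x, rows with k_y.
    """
    kx, ky = float(k_n[0]), float(k_n[1])
    sc, sr = kx / system.dk, ky / system.dk
    qr, qc = int(round(sr)), int(round(sc))
    return (qr, qc), (sr - qr, sc - qc)


def shift_spectrum(spectrum: ComplexField, k_n, system: OpticalSystem) -> ComplexField:
    """Return O(k − k_n) with the shift quantized to the grid.

    Pixels shifted in from outside the sampled band are zero; the sub-pixel
    quantization residual is recorded on the returned field as
    ``quantization_residual``.
    """
    if spectrum.domain != "frequency":
        raise ValidationError("shift_spectrum expects a frequency-domain field")
    (qr, qc), resid = quantize_shift(k_n, system)
    vals = np.zeros_like(spectrum.values)
    rows, cols = vals.shape

    def _rng(shift, size):
        # destination/source ranges for a zero-fill shift by `shift`
        dst = slice(max(shift, 0), min(size + shift, size))
        src = slice(max(-shift, 0), min(size - shift, size))
        return dst, src

    dr, sr_ = _rng(qr, rows)
    dc, sc_ = _rng(qc, cols)
    vals[dr, dc] = spectrum.values[sr_, sc_]
    out = ComplexField(vals, "frequency", spectrum.sampling)
    out.quantization_residual = resid  # type: ignore[attr-defined]
    return out


def _window_shift(k_n, system: OpticalSystem) -> tuple[int, int]:
    """Center of the pupil window in the hires spectrum for illumination k_n.

    The shifted spectrum O(k − k_n) sampled on the pupil window around zero
    frequency equals the window of O centered at −k_n.
    """
    (qr, qc), _ = quantize_shift(k_n, system)
    return (-qr, -qc)


def forward_image(
    object_spectrum: ComplexField,
    pupil: Pupil,
    k_n,
    system: OpticalSystem,
    led_index: int | None = None,
) -> np.ndarray:
    """Simulated camera intensity for one LED (Eq. of the forward model)."""
    if object_spectrum.domain != "frequency":
        raise ValidationError("forward_image expects a frequency-domain object spectrum")
    m = pupil.shape
    if m != system.lores_shape:
        raise DimensionMismatchError(
            f"pupil grid {m} does not match the low-res grid {system.lores_shape}"
        )
    shift = _window_shift(k_n, system)
    try:
        window = crop_window(object_spectrum.values, m, shift)
    except ValueError as err:
        who = f"LED {led_index}" if led_index is not None else f"k_n = {tuple(k_n)}"
        raise OutOfBandError(f"pupil window for {who} leaves the sampled spectrum: {err}")
    scale = decimation_scale(object_spectrum.shape, m)
    field_lo = ifft2c(window * pupil.complex_value) * scale
    return np.abs(field_lo) ** 2


def simulate_dataset(
    obj: ComplexField,
    pupil: Pupil,
    leds: LEDArray,
    system: OpticalSystem,
    noise: NoiseSpec | None = None,
    seed: int | None = None,
) -> AcquisitionStack:
    """Simulate one full LED scan: one intensity image per LED in scan order."""
    spectrum = obj.to_frequency()
    if spectrum.shape != tuple(system.hires_shape):
        raise DimensionMismatchError(
            f"object grid {spectrum.shape} does not match hires_shape {system.hires_shape}"
        )
    order = leds.scan_order
    wavevectors = leds.wavevectors[order]
    images = np.empty((len(order),) + tuple(system.lores_shape))
    residuals = np.empty((len(order), 2))
    for i, k_n in enumerate(wavevectors):
        images[i] = forward_image(spectrum, pupil, k_n, system, led_index=int(order[i]))
        residuals[i] = quantize_shift(k_n, system)[1]
    if noise is not None and noise.enabled:
        rng = np.random.default_rng(seed)
        images = np.stack([noise.apply(im, rng) for im in images])
    return AcquisitionStack(
        images=images,
        wavevectors=wavevectors,
        system=system,
        leds=leds,
        noise_seed=seed if (noise is not None and noise.enabled) else None,
        shift_residuals=residuals,
    )


def upsample_intensity(intensity: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Upsample a non-negative intensity image by Fourier zero-padding of its
    square root, then re-squaring (keeps the result non-negative)."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValidationError("intensity must be non-negative")
    if tuple(intensity.shape) == tuple(target_shape):
        return intensity
    amp = np.sqrt(intensity)
    spec = fft2c(amp.astype(complex))
    big = ifft2c(pad_spectrum(spec, target_shape)) / decimation_scale(
        target_shape, intensity.shape
    )
    return np.abs(big) ** 2
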