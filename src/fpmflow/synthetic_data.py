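"""Synthetic benchmark generation: complex phantoms, defocused pupils and
full acquisition stacks.

The generator emulates the simulated-experiment design of the method's
validation study: a complex object whose amplitude and phase carry two
*independent* structured patterns (standing in for the classic
cameraman/street-map pair, which can be supplied from files but is never
bundled), an LED scan over a rectangular grid, and a pupil whose phase is
pure defocus at a chosen defocus distance (25/50/75 µm planes).

Default desk-scale geometry: 64×64 high-resolution grid, upsampling 4,
9×9 LEDs at 4 mm pitch, 100 mm below the sample; λ = 532 nm, NA = 0.1,
3.45 µm camera pixels behind an effective 4× magnification.  The full
15×15-LED scan of the reference hardware is available by passing
``leds=(15, 15)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, ValidationError
from .forward_model import AcquisitionStack, ComplexField, NoiseSpec, simulate_dataset
from .optics import (
    LEDArray,
    OpticalSystem,
    Pupil,
    ZernikeBasis,
    build_pupil,
    defocus_to_zernike,
    make_ctf,
)

__all__ = [
    "PhantomSpec",
    "BenchmarkCase",
    "default_system",
    "default_leds",
    "make_phantom",
    "make_defocus_scenario",
    "make_benchmark_case",
]

#: canonical acquisition constants: λ = 0.532 µm, NA = 0.1, 3.45 µm camera
#: pixel at 4× magnification, LED plane 100 mm below the sample, 4 mm pitch
WAVELENGTH_UM = 0.532
NA = 0.1
CAMERA_PIXEL_UM = 3.45
MAGNIFICATION = 4.0
LED_HEIGHT_MM = 100.0
LED_PITCH_MM = 4.0


def default_system(hires: int = 64, upsampling: int = 4) -> OpticalSystem:
    """Desk-scale optical system with the canonical acquisition constants."""
    pixel_lo = CAMERA_PIXEL_UM / MAGNIFICATION
    return OpticalSystem(
        wavelength=WAVELENGTH_UM,
        na=NA,
        pixel_size_obj=pixel_lo / upsampling,
        hires_shape=(hires, hires),
        upsampling=upsampling,
    )


def default_leds(grid_shape: tuple[int, int] = (9, 9)) -> LEDArray:
    return LEDArray(
        grid_shape=grid_shape,
        pitch=LED_PITCH_MM,
        height=LED_HEIGHT_MM,
        wavelength=WAVELENGTH_UM,
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a complex phantom.

    ``amplitude_pattern`` and ``phase_pattern`` are chosen independently
    from {"checker", "blobs", "stripes"} or a path to a grayscale image
    file; ``phase_scale`` s maps the phase pattern into [−π·s, π·s].
    """

    shape: tuple[int, int] = (64, 64)
    amplitude_pattern: str = "blobs"
    phase_pattern: str = "blobs"
    amplitude_range: tuple[float, float] = (0.5, 1.0)
    phase_scale: float = 0.5
    seed: int = 0

    def __post_init__(self):
        a_min, a_max = self.amplitude_range
        if not (0 < a_min <= a_max <= 1):
            raise ValidationError("amplitude range must satisfy 0 < a_min <= a_max <= 1")
        if not 0 <= self.phase_scale <= 1:
            raise ValidationError("phase_scale must lie in [0, 1]")


def _pattern(name: str, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """A structured image in [0, 1]."""
    rows, cols = shape
    if name == "checker":
        tile = max(2, rows // 8)
        yy, xx = np.mgrid[0:rows, 0:cols]
        base = (((yy // tile) + (xx // tile)) % 2).astype(float)
        # soften edges slightly so the pattern is band-limited-ish
        return ndimage.gaussian_filter(base, sigma=0.5)
    if name == "blobs":
        field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=rows / 16)
        lo, hi = field_.min(), field_.max()
        return (field_ - lo) / (hi - lo)
    if name == "stripes":
        # text-like bars: random-width horizontal stripes with gaps
        img = np.zeros(shape)
        row = 1
        while row < rows - 2:
            h = int(rng.integers(1, max(2, rows // 12)))
            gap = int(rng.integers(1, max(2, rows // 16)))
            c0 = int(rng.integers(0, cols // 2))
            c1 = int(rng.integers(cols // 2, cols))
            img[row : min(row + h, rows - 1), c0:c1] = 1.0
            row += h + gap
        return ndimage.gaussian_filter(img, sigma=0.7)
    path = Path(name)
    if path.exists():
        from imageio.v3 import imread

        img = np.asarray(imread(path), dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=-1)
        img = (img - img.min()) / max(img.max() - img.min(), 1e-12)
        zoom = (shape[0] / img.shape[0], shape[1] / img.shape[1])
        return np.clip(ndimage.zoom(img, zoom, order=1), 0.0, 1.0)
    raise ConfigurationError(f"unknown phantom pattern {name!r} (not a builtin or a file)")


def make_phantom(spec: PhantomSpec) -> ComplexField:
    """Deterministic complex phantom with independent amplitude and phase."""
    rng = np.random.default_rng(spec.seed)
    amp_pat = _pattern(spec.amplitude_pattern, spec.shape, rng)
    ph_pat = _pattern(spec.phase_pattern, spec.shape, rng)
    a_min, a_max = spec.amplitude_range
    amplitude = a_min + (a_max - a_min) * amp_pat
    phase = (2.0 * ph_pat - 1.0) * np.pi * spec.phase_scale
    return ComplexField(amplitude * np.exp(1j * phase), "space")


def make_defocus_scenario(
    z: float,
    system: OpticalSystem,
    basis: ZernikeBasis | None = None,
    model: str = "paraxial",
) -> Pupil:
    """Pupil with ideal CTF amplitude and pure defocus phase for a defocus
    distance ``z`` in µm (the 25/50/75 µm planes of the benchmark, or any
    other value)."""
    if basis is None:
        basis = ZernikeBasis.up_to_order(4)
    coeffs = np.zeros(len(basis))
    coeffs[basis.index_of(2, 0)] = defocus_to_zernike(z, system, model=model)
    return build_pupil(make_ctf(system), basis, coeffs, system)


@dataclass
class BenchmarkCase:
    """Reproducible simulation triplet plus the parameters that made it."""

    ground_truth: ComplexField
    pupil: Pupil
    stack: AcquisitionStack
    system: OpticalSystem
    leds: LEDArray
    metadata: dict = field(default_factory=dict)


def make_benchmark_case(
    z: float = 50.0,
    spec: PhantomSpec | None = None,
    leds: LEDArray | tuple[int, int] = (9, 9),
    system: OpticalSystem | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> BenchmarkCase:
    """Simulate a full defocus-aberrated acquisition with known ground truth."""
    system = system or default_system()
    if not isinstance(leds, LEDArray):
        leds = default_leds(tuple(leds))
    spec = spec or PhantomSpec(shape=tuple(system.hires_shape), seed=seed)
    if tuple(spec.shape) != tuple(system.hires_shape):
        raise ConfigurationError(
            f"phantom shape {spec.shape} does not match hires grid {system.hires_shape}"
        )
    truth = make_phantom(spec)
    pupil = make_defocus_scenario(z, system)
    stack = simulate_dataset(truth, pupil, leds, system, noise=noise, seed=seed)
    meta = {
        "defocus_um": z,
        "seed": seed,
        "phantom": {
            "shape": list(spec.shape),
            "amplitude_pattern": spec.amplitude_pattern,
            "phase_pattern": spec.phase_pattern,
            "amplitude_range": list(spec.amplitude_range),
            "phase_scale": spec.phase_scale,
            "seed": spec.seed,
        },
        "system": {
            "wavelength_um": system.wavelength,
            "na": system.na,
            "pixel_size_obj_um": system.pixel_size_obj,
            "hires_shape": list(system.hires_shape),
            "upsampling": system.upsampling,
        },
        "leds": {
            "grid_shape": list(leds.grid_shape),
            "pitch_mm": leds.pitch,
            "height_mm": leds.height,
        },
        "noise": None
        if noise is None or not noise.enabled
        else {"photon_budget": noise.photon_budget, "read_noise_std": noise.read_noise_std},
        "defocus_coeff_rad": float(pupil.zernike_coeffs[pupil.basis.index_of(2, 0)]),
    }
    return BenchmarkCase(
        ground_truth=truth, pupil=pupil, stack=stack, system=system, leds=leds, metadata=meta
    )
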