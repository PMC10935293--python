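"""Classical iterative FPM reconstruction (no aberration correction).

Alternating-projection spectrum stitching: for each LED the current
high-resolution spectrum estimate is windowed and low-pass filtered by the
pupil to predict the camera field (Eq. 3-style estimate); the predicted
modulus is replaced by the measured one, and the corrected patch is written
back into the shifted spectrum window (Eq. 4-style update).  This is a pure
Fourier-magnitude-replacement write-back — no ePIE step size or
conjugate-pupil weighting — and serves as the "without aberration
correction" baseline when run with the ideal CTF on aberrated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, OutOfBandError, ValidationError
from .fourier import (
    crop_window,
    decimation_scale,
    fft2c,
    fourier_upsample,
    ifft2c,
    window_bounds,
)
from .forward_model import AcquisitionStack, ComplexField, _window_shift
from .optics import OpticalSystem, Pupil

__all__ = ["ReconState", "estimate_lowres", "spectrum_update", "reconstruct_classic"]

_PUPIL_EPS = 1e-12


@dataclass
class ReconState:
    """Current high-resolution spectrum estimate and convergence history."""

    spectrum: np.ndarray  # (M, M) complex, centered frequency layout
    system: OpticalSystem
    iteration: int = 0
    convergence_trace: list = field(default_factory=list)  # relative spectrum change
    misfit_trace: list = field(default_factory=list)  # sum_n || |g_n|^2 - I_n ||^2

    @property
    def object_estimate(self) -> ComplexField:
        return ComplexField(ifft2c(self.spectrum), "space", self.system.pixel_size_obj)


def estimate_lowres(
    state: ReconState, pupil: Pupil, k_n, system: OpticalSystem
) -> ComplexField:
    """Predicted camera-plane complex field for illumination k_n."""
    shift = _window_shift(k_n, system)
    try:
        window = crop_window(state.spectrum, pupil.shape, shift)
    except ValueError as err:
        raise OutOfBandError(str(err))
    scale = decimation_scale(state.spectrum.shape, pupil.shape)
    return ComplexField(
        ifft2c(window * pupil.complex_value) * scale, "space", system.pixel_size_cam
    )


def spectrum_update(
    state: ReconState, pupil: Pupil, k_n, measured: np.ndarray, system: OpticalSystem
) -> ReconState:
    """Magnitude-replacement update of one pupil window (in place).

    The predicted field keeps its phase but takes the measured modulus
    √I; the resulting patch, divided by the pupil where it has support,
    replaces the spectrum inside the support.  Spectrum pixels outside the
    pupil support are untouched.  Zero-modulus prediction pixels keep phase
    0 by convention.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.shape != pupil.shape:
        raise ValidationError(
            f"measured image shape {measured.shape} does not match pupil {pupil.shape}"
        )
    if np.any(measured < 0):
        raise ValidationError("measured intensities must be non-negative")
    g = estimate_lowres(state, pupil, k_n, system).values
    mod = np.abs(g)
    phase_factor = np.where(mod > 0, g / np.where(mod > 0, mod, 1.0), 1.0)
    g_new = np.sqrt(measured) * phase_factor
    scale = decimation_scale(state.spectrum.shape, pupil.shape)
    patch = fft2c(g_new) / scale
    c = pupil.complex_value
    inside = pupil.support & (np.abs(c) > _PUPIL_EPS)
    shift = _window_shift(k_n, system)
    sr, sc = window_bounds(state.spectrum.shape, pupil.shape, shift)
    window = state.spectrum[sr, sc]
    window[inside] = patch[inside] * np.conj(c[inside]) / (np.abs(c[inside]) ** 2)
    state.spectrum[sr, sc] = window
    return state


def _initial_spectrum(stack: AcquisitionStack, system: OpticalSystem, init: str) -> np.ndarray:
    M = tuple(system.hires_shape)
    if init == "lowres_upsample":
        amp = np.sqrt(stack.images[stack.center_index])
        return fft2c(fourier_upsample(amp, M))
    if init == "ones":
        return fft2c(np.ones(M, dtype=complex))
    raise ConfigurationError(f"unknown initialization {init!r}")


def _data_misfit(state: ReconState, pupil: Pupil, stack: AcquisitionStack) -> float:
    total = 0.0
    for k_n, measured in zip(stack.wavevectors, stack.images):
        g = estimate_lowres(state, pupil, k_n, stack.system).values
        total += float(np.sum((np.abs(g) ** 2 - measured) ** 2))
    return total


def reconstruct_classic(
    stack: AcquisitionStack,
    system: OpticalSystem,
    pupil: Pupil,
    n_iters: int = 50,
    init: str = "lowres_upsample",
    tol: float = 1e-6,
    track_misfit: bool = True,
) -> tuple[ComplexField, ReconState]:
    """Run alternating-projection sweeps over all LEDs.

    Returns the inverse transform of the final spectrum plus the state with
    per-sweep convergence and data-misfit traces.  Stops after ``n_iters``
    sweeps or when the relative spectrum change drops below ``tol``.
    """
    if n_iters < 0:
        raise ConfigurationError("n_iters must be non-negative")
    state = ReconState(spectrum=_initial_spectrum(stack, system, init), system=system)
    for sweep in range(n_iters):
        if track_misfit:
            state.misfit_trace.append(_data_misfit(state, pupil, stack))
        previous = state.spectrum.copy()
        for k_n, measured in zip(stack.wavevectors, stack.images):
            spectrum_update(state, pupil, k_n, measured, system)
        state.iteration = sweep + 1
        denom = np.linalg.norm(previous)
        change = np.linalg.norm(state.spectrum - previous) / (denom if denom > 0 else 1.0)
        state.convergence_trace.append(float(change))
        if change < tol:
            break
    return state.object_estimate, state
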