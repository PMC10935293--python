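"""Aberration-correcting FPM reconstruction by Wirtinger-Flow training
(the INN_IWF scheme): a differentiable forward model whose learnable
parameters are the complex object (real/imaginary high-res maps) and the
pupil (CTF amplitude map plus Zernike phase coefficients), trained by
plain gradient descent with an alternating-update (AU) schedule.

Per LED n the computation chain is

    φ_l = O window(k_n) ⊙ C                      (LUDA forward unit)
    a    = F⁻¹ φ_l
    φ_m = φ_l − Δ · F{ (|a|² − y) ⊙ a }          (WFM: one Wirtinger-Flow
                                                  step on ‖|a|²−y‖²)
    f    = ∠ F⁻¹ φ_m
    φ_h = F{ √y · e^{i f} }                      (WFN: intensity constraint)
    loss = mean |φ_h − φ_l|²                     (spectral MSE)

with y the measured intensity on the pupil-window grid.  Gradients with
respect to all four parameter blocks are hand-derived Wirtinger adjoints
(convention: for real loss L and complex variable w the propagated quantity
is ∂L/∂w̄; for a real leaf x entering as w = x resp. w = ix the real
gradient is 2·Re resp. 2·Im of it).  They are validated against central
finite differences in the test suite.

The AU schedule alternates epochs that update only the object (learning
rate ``lr_sample``) with epochs that update only the pupil
(``lr_pupil``); the CTF amplitude is projected to be non-negative after
each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    ConfigurationError,
    DimensionMismatchError,
    DivergenceError,
    OutOfBandError,
    ValidationError,
)
from .fourier import decimation_scale, fft2c, fourier_upsample, ifft2c, window_bounds
from .forward_model import AcquisitionStack, ComplexField, _window_shift, upsample_intensity
from .optics import OpticalSystem, Pupil, ZernikeBasis, make_ctf, pupil_coords

__all__ = [
    "IWFParams",
    "IWFBatch",
    "TrainConfig",
    "TrainResult",
    "luda_forward",
    "wfm_update",
    "wfn_constraint",
    "iwf_loss",
    "loss_and_gradients",
    "train_inn_iwf",
]

logger = logging.getLogger("fpmflow")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class IWFParams:
    """Learnable parameters: the object split into real/imaginary parts,
    the CTF amplitude map, and the Zernike phase coefficients."""

    sample_real: np.ndarray  # (M, M)
    sample_imag: np.ndarray  # (M, M)
    ctf_amplitude: np.ndarray  # (m, m) >= 0
    zernike_coeffs: np.ndarray  # (n_terms,)

    def __post_init__(self):
        self.sample_real = np.asarray(self.sample_real, dtype=float)
        self.sample_imag = np.asarray(self.sample_imag, dtype=float)
        self.ctf_amplitude = np.asarray(self.ctf_amplitude, dtype=float)
        self.zernike_coeffs = np.asarray(self.zernike_coeffs, dtype=float)
        for name in ("sample_real", "sample_imag", "ctf_amplitude", "zernike_coeffs"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValidationError(f"{name} contains non-finite values")
        if self.sample_real.shape != self.sample_imag.shape:
            raise DimensionMismatchError("sample_real/sample_imag shapes differ")

    @property
    def object_values(self) -> np.ndarray:
        return self.sample_real + 1j * self.sample_imag

    def copy(self) -> "IWFParams":
        return IWFParams(
            self.sample_real.copy(),
            self.sample_imag.copy(),
            self.ctf_amplitude.copy(),
            self.zernike_coeffs.copy(),
        )


@dataclass
class IWFBatch:
    """Intermediate spectra of one LUDA→WFM→WFN pass (diagnostic record)."""

    phi_l: np.ndarray
    phi_m: np.ndarray
    phi_h: np.ndarray
    y: np.ndarray
    a: np.ndarray
    f_wf: np.ndarray


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters.

    delta is the Wirtinger step Δ inside the WFM module; measured
    intensities are normalized to unit mean before training (the output
    object is rescaled back), which makes Δ = 1 a well-conditioned default.
    ``au_schedule`` is a cyclic phase pattern; the default alternates
    object and pupil epochs starting with the object.
    """

    epochs: int = 2000
    lr_sample: float = 100.0
    lr_pupil: float = 10.0
    delta: float = 1.0
    au_schedule: tuple[str, ...] = ("sample", "pupil")
    zernike_n_max: int = 4
    normalization: str = "unit"
    upsample_method: str = "fourier"
    mode: str = "end_to_end"  # or "detached": φ_h treated as a fixed target
    normalize_input: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.delta < 0 or self.lr_sample < 0 or self.lr_pupil < 0:
            raise ConfigurationError("delta and learning rates must be non-negative")
        if self.mode not in ("end_to_end", "detached"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for phase in self.au_schedule:
            if phase not in ("sample", "pupil"):
                raise ConfigurationError(f"unknown AU phase {phase!r}")


@dataclass
class TrainResult:
    object_estimate: ComplexField
    pupil: Pupil
    loss_trace: np.ndarray
    params: IWFParams
    coeff_trace: np.ndarray  # (epochs+1, n_terms)


# ---------------------------------------------------------------------------
# single-LED building blocks (reference implementations used by the tests
# and by the vectorized trainer below)
# ---------------------------------------------------------------------------


def _pupil_complex(params: IWFParams, zmaps: np.ndarray) -> np.ndarray:
    # zmaps are already zero outside the pupil support, so the phase obeys
    # the zero-outside-support convention; the amplitude is a whole map
    phase = np.tensordot(params.zernike_coeffs, zmaps, axes=1)
    return params.ctf_amplitude * np.exp(1j * phase)


def luda_forward(
    params: IWFParams,
    k_n,
    system: OpticalSystem,
    basis: ZernikeBasis,
) -> np.ndarray:
    """Pre-update spectrum φ_l = O window(k_n) ⊙ C on the pupil grid.

    Computed through the real/imaginary product expansion
    (Or⊙Cr − Oi⊙Ci) + j(Or⊙Ci + Oi⊙Cr); identical to the native complex
    product.  Includes the value-preserving decimation factor so that
    |F⁻¹ φ_l|² lives on the measured-intensity scale.
    """
    m = system.lores_shape
    rho, theta, support = pupil_coords(system, m)
    zmaps = basis.design_matrix(rho, theta, support)
    C = _pupil_complex(params, zmaps)
    O = fft2c(params.object_values)
    shift = _window_shift(k_n, system)
    try:
        sr, sc = window_bounds(O.shape, m, shift)
    except ValueError as err:
        raise OutOfBandError(str(err))
    W = O[sr, sc]
    scale = decimation_scale(O.shape, m)
    # real/imag expansion of (Wr + jWi)(Cr + jCi)
    Wr, Wi, Cr, Ci = W.real, W.imag, C.real, C.imag
    return ((Wr * Cr - Wi * Ci) + 1j * (Wr * Ci + Wi * Cr)) * scale


def wfm_update(phi_l: np.ndarray, y: np.ndarray, delta: float) -> np.ndarray:
    """One Wirtinger-Flow gradient step on the intensity misfit ‖|a|²−y‖²
    with a = F⁻¹ φ_l:   φ_m = φ_l − Δ·F{(|a|² − y) ⊙ a}."""
    phi_l = np.asarray(phi_l, dtype=complex)
    y = np.asarray(y, dtype=float)
    if phi_l.shape != y.shape:
        raise DimensionMismatchError(
            f"phi_l shape {phi_l.shape} does not match intensity shape {y.shape}"
        )
    a = ifft2c(phi_l)
    return phi_l - delta * fft2c((np.abs(a) ** 2 - y) * a)


def wfn_constraint(
    phi_m: np.ndarray,
    measured_intensity: np.ndarray,
    system: OpticalSystem | None = None,
) -> np.ndarray:
    """Intensity constraint: keep the phase of F⁻¹ φ_m, replace the modulus
    by √I (I upsampled to the φ grid if coarser), and transform back."""
    phi_m = np.asarray(phi_m, dtype=complex)
    measured = np.asarray(measured_intensity, dtype=float)
    if np.any(measured < 0):
        raise ValidationError("measured intensities must be non-negative")
    y = upsample_intensity(measured, phi_m.shape)
    b = ifft2c(phi_m)
    mod = np.abs(b)
    unit = np.where(mod > 0, b / np.where(mod > 0, mod, 1.0), 1.0)
    return fft2c(np.sqrt(y) * unit)


def iwf_loss(phi_h: np.ndarray, phi_l: np.ndarray) -> float:
    """Spectral mean-square error between post- and pre-update spectra."""
    phi_h = np.asarray(phi_h)
    phi_l = np.asarray(phi_l)
    if phi_h.shape != phi_l.shape:
        raise DimensionMismatchError("phi_h and phi_l shapes differ")
    return float(np.mean(np.abs(phi_h - phi_l) ** 2))


# ---------------------------------------------------------------------------
# vectorized loss + gradients over all LEDs
# ---------------------------------------------------------------------------


def _gather_indices(system: OpticalSystem, wavevectors: np.ndarray):
    """Row/col index arrays of each LED's pupil window in the hires grid."""
    M = tuple(system.hires_shape)
    m = system.lores_shape
    rows = np.empty((len(wavevectors), m[0]), dtype=np.intp)
    cols = np.empty((len(wavevectors), m[1]), dtype=np.intp)
    for i, k_n in enumerate(wavevectors):
        shift = _window_shift(k_n, system)
        try:
            sr, sc = window_bounds(M, m, shift)
        except ValueError as err:
            raise OutOfBandError(f"LED {i}: {err}")
        rows[i] = np.arange(sr.start, sr.stop)
        cols[i] = np.arange(sc.start, sc.stop)
    return rows, cols


def loss_and_gradients(
    params: IWFParams,
    y: np.ndarray,  # (N, m, m) measured intensities (already normalized)
    rows: np.ndarray,
    cols: np.ndarray,
    zmaps: np.ndarray,
    support: np.ndarray,
    delta: float,
    mode: str = "end_to_end",
    want_batch: bool = False,
    scale: float | None = None,
):
    """Total loss (mean over LEDs and pixels) and Wirtinger gradients for
    every parameter block, vectorized over the LED axis.

    ``scale`` is the amplitude factor applied inside the LUDA product
    (defaults to the value-preserving decimation factor; the trainer folds
    its intensity normalization into it).  Returns ``(loss, grads)`` with
    ``grads`` a dict holding ``sample_real, sample_imag, ctf_amplitude,
    zernike_coeffs``.
    """
    M = params.sample_real.shape
    N, mr, mc = y.shape
    if scale is None:
        scale = decimation_scale(M, (mr, mc))
    P = N * mr * mc

    phase = np.tensordot(params.zernike_coeffs, zmaps, axes=1)
    eiphi = np.exp(1j * phase)
    C = params.ctf_amplitude * eiphi

    o = params.object_values
    O = fft2c(o)
    W = O[rows[:, :, None], cols[:, None, :]]  # (N, m, m)

    phi_l = W * C[None] * scale
    a = ifft2c(phi_l)
    r = np.abs(a) ** 2 - y
    phi_m = phi_l - delta * fft2c(r * a)
    b = ifft2c(phi_m)
    mod_b = np.abs(b)
    unit = np.where(mod_b > 0, b / np.where(mod_b > 0, mod_b, 1.0), 1.0)
    sq = np.sqrt(y)
    phi_h = fft2c(sq * unit)
    e = phi_h - phi_l
    loss = float(np.sum(np.abs(e) ** 2) / P)

    # ---- reverse pass (Wirtinger adjoints, G_w = dL/dw̄) ----
    G_e = e / P
    G_phi_l = -G_e
    if mode == "end_to_end":
        G_phi_h = G_e
        G_su = ifft2c(G_phi_h)  # adjoint of fft2c
        G_u = sq * G_su
        with np.errstate(invalid="ignore", divide="ignore"):
            G_b = np.where(
                mod_b > 0,
                (G_u - unit**2 * np.conj(G_u)) / (2.0 * np.where(mod_b > 0, mod_b, 1.0)),
                0.0,
            )
        G_phi_m = fft2c(G_b)
        G_phi_l = G_phi_l + G_phi_m
        G_t = -delta * ifft2c(G_phi_m)
        G_a = np.conj(G_t) * a**2 + G_t * (2.0 * np.abs(a) ** 2 - y)
        G_phi_l = G_phi_l + fft2c(G_a)

    G_W = np.conj(C)[None] * G_phi_l * scale
    G_C = np.sum(np.conj(W) * G_phi_l, axis=0) * scale

    g_camp = 2.0 * np.real(G_C * np.conj(eiphi))
    g_phase = 2.0 * np.imag(G_C * np.conj(C))
    g_zc = np.tensordot(zmaps, g_phase, axes=([1, 2], [0, 1]))

    G_O = np.zeros(M, dtype=complex)
    np.add.at(G_O, (rows[:, :, None], cols[:, None, :]), G_W)
    G_o = ifft2c(G_O)
    g_or = 2.0 * np.real(G_o)
    g_oi = 2.0 * np.imag(G_o)

    grads = {
        "sample_real": g_or,
        "sample_imag": g_oi,
        "ctf_amplitude": g_camp,
        "zernike_coeffs": g_zc,
    }
    if want_batch:
        f_wf = np.angle(b)
        batch = IWFBatch(phi_l=phi_l, phi_m=phi_m, phi_h=phi_h, y=y, a=a, f_wf=f_wf)
        return loss, grads, batch
    return loss, grads


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def default_init(
    stack: AcquisitionStack,
    system: OpticalSystem,
    basis: ZernikeBasis,
) -> IWFParams:
    """Deterministic initialization: object from the Fourier-upsampled square
    root of the center-LED image; ideal binary CTF amplitude; zero Zernike
    coefficients."""
    amp = np.sqrt(stack.images[stack.center_index])
    obj = fourier_upsample(amp, tuple(system.hires_shape))
    return IWFParams(
        sample_real=obj.real,
        sample_imag=obj.imag,
        ctf_amplitude=make_ctf(system, system.lores_shape),
        zernike_coeffs=np.zeros(len(basis)),
    )


def train_inn_iwf(
    stack: AcquisitionStack,
    system: OpticalSystem,
    init: IWFParams | None = None,
    config: TrainConfig | None = None,
    basis: ZernikeBasis | None = None,
) -> TrainResult:
    """Gradient-descent training with the alternating-update schedule.

    Each epoch runs the full LED batch through LUDA→WFM→WFN, accumulates the
    spectral-MSE loss gradients, and updates only the parameter block the AU
    schedule assigns to that epoch.  Returns the reconstructed object, the
    recovered pupil and the per-epoch loss trace.
    """
    config = config or TrainConfig()
    if basis is None:
        basis = ZernikeBasis.up_to_order(config.zernike_n_max, config.normalization)

    m = system.lores_shape
    if stack.images.shape[1:] != tuple(m):
        y = np.stack([upsample_intensity(im, m) for im in stack.images])
    else:
        y = stack.images.astype(float)
    norm = float(np.mean(y)) if config.normalize_input else 1.0
    if norm <= 0:
        raise ValidationError("measured stack has non-positive mean intensity")
    # intensities are normalized to unit mean; the matching 1/sqrt(norm)
    # amplitude factor is folded into the forward scale constant so that the
    # learnable object stays in the caller's units throughout
    y = y / norm
    scale = decimation_scale(tuple(system.hires_shape), m) / float(np.sqrt(norm))

    rho, theta, support = pupil_coords(system, m)
    zmaps = basis.design_matrix(rho, theta, support)
    rows, cols = _gather_indices(system, stack.wavevectors)

    if init is None:
        params = default_init(stack, system, basis)
    else:
        params = init.copy()
    if len(params.zernike_coeffs) != len(basis):
        raise DimensionMismatchError(
            f"init has {len(params.zernike_coeffs)} Zernike coefficients, "
            f"basis has {len(basis)}"
        )

    loss_trace = np.empty(config.epochs)
    coeff_trace = np.empty((config.epochs + 1, len(basis)))
    coeff_trace[0] = params.zernike_coeffs
    schedule = config.au_schedule
    for epoch in range(config.epochs):
        loss, grads = loss_and_gradients(
            params, y, rows, cols, zmaps, support, config.delta, config.mode, scale=scale
        )
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        loss_trace[epoch] = loss
        phase_name = schedule[epoch % len(schedule)]
        if phase_name == "sample":
            params.sample_real = params.sample_real - config.lr_sample * grads["sample_real"]
            params.sample_imag = params.sample_imag - config.lr_sample * grads["sample_imag"]
        else:
            params.ctf_amplitude = np.clip(
                params.ctf_amplitude - config.lr_pupil * grads["ctf_amplitude"], 0.0, None
            )
            params.zernike_coeffs = params.zernike_coeffs - config.lr_pupil * grads["zernike_coeffs"]
        coeff_trace[epoch + 1] = params.zernike_coeffs
        if epoch % 10 == 0 or epoch == config.epochs - 1:
            logger.info("epoch %4d [%s] loss %.6e", epoch, phase_name, loss)

    obj = ComplexField(params.object_values, "space", system.pixel_size_obj)
    phase = np.tensordot(params.zernike_coeffs, zmaps, axes=1)
    pupil = Pupil(
        amplitude=params.ctf_amplitude,
        phase=phase,
        support=support,
        basis=basis,
        zernike_coeffs=params.zernike_coeffs.copy(),
    )
    return TrainResult(
        object_estimate=obj,
        pupil=pupil,
        loss_trace=loss_trace,
        params=params,
        coeff_trace=coeff_trace,
    )
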