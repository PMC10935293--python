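"""Optical system geometry, LED illumination, CTF and Zernike pupil models.

Frequency bookkeeping
---------------------
All spatial frequencies are expressed in cycles/µm.  The coherent passband
of the objective is the disk ``|k| < NA / λ`` (the coherent cutoff); the
angular wavenumber ``k0 = 2π/λ`` only enters optical *phase* calculations
such as defocus.  Pupil-disk coordinates map ``|k| = NA/λ`` to ``ρ = 1``.

Zernike terms are addressed by their radial order ``n`` and azimuthal
frequency ``m`` (``m > 0``: cos, ``m < 0``: sin), which avoids the
Noll-vs-ANSI single-index ambiguity; a sequential single index ``j`` is kept
for serialization, assigned so that odd ``j`` carries the cosine term and
even ``j`` the sine term of each ``(n, |m|)`` pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    ConfigurationError,
    InvalidGeometryError,
    InvalidIndexError,
    DimensionMismatchError,
    ValidationError,
)

__all__ = [
    "OpticalSystem",
    "LEDArray",
    "ZernikeBasis",
    "Pupil",
    "led_wavevector",
    "make_ctf",
    "zernike_radial",
    "zernike_phase",
    "build_pupil",
    "ideal_pupil",
    "pupil_coords",
    "defocus_to_zernike",
]


# ---------------------------------------------------------------------------
# optical system
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalSystem:
    """Geometry and sampling of the imaging system.

    Parameters
    ----------
    wavelength:
        Illumination wavelength in µm.
    na:
        Numerical aperture of the objective (0 < NA < 1).
    pixel_size_obj:
        Effective object-plane sampling of the *high-resolution* grid in µm
        (camera pixel / magnification / upsampling).
    hires_shape:
        Shape of the high-resolution reconstruction grid.
    upsampling:
        Integer ratio between high-resolution and camera grids.
    """

    wavelength: float
    na: float
    pixel_size_obj: float
    hires_shape: tuple[int, int] = (64, 64)
    upsampling: int = 4

    def __post_init__(self):
        if self.wavelength <= 0:
            raise InvalidGeometryError(f"wavelength must be positive, got {self.wavelength}")
        if not 0 < self.na < 1:
            raise ConfigurationError(f"numerical aperture must lie in (0, 1), got {self.na}")
        if self.pixel_size_obj <= 0:
            raise InvalidGeometryError("pixel_size_obj must be positive")
        if self.upsampling < 1:
            raise ConfigurationError("upsampling factor must be a positive integer")
        if any(s % self.upsampling for s in self.hires_shape):
            raise ConfigurationError(
                f"hires_shape {self.hires_shape} not divisible by upsampling {self.upsampling}"
            )
        if self.cutoff >= self.nyquist:
            raise ConfigurationError(
                f"coherent cutoff {self.cutoff:.4g} cycles/µm exceeds the Nyquist "
                f"frequency {self.nyquist:.4g} of the high-resolution grid"
            )

    @property
    def k0(self) -> float:
        """Angular wavenumber 2π/λ in rad/µm."""
        return 2.0 * math.pi / self.wavelength

    @property
    def cutoff(self) -> float:
        """Coherent cutoff NA/λ in cycles/µm."""
        return self.na / self.wavelength

    @property
    def nyquist(self) -> float:
        """Nyquist frequency of the high-resolution grid in cycles/µm."""
        return 0.5 / self.pixel_size_obj

    @property
    def lores_shape(self) -> tuple[int, int]:
        return tuple(s // self.upsampling for s in self.hires_shape)

    @property
    def pixel_size_cam(self) -> float:
        """Object-plane size of one camera pixel (µm)."""
        return self.pixel_size_obj * self.upsampling

    @property
    def dk(self) -> float:
        """Frequency sampling of the high-res grid (cycles/µm); the low-res
        grid, being a central crop of the same spectrum, shares it."""
        return 1.0 / (self.hires_shape[0] * self.pixel_size_obj)

    def freq_grids(self, grid_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Centered (ky, kx) coordinate grids in cycles/µm."""
        rows, cols = grid_shape
        ky = (np.arange(rows) - rows // 2) * self.dk
        kx = (np.arange(cols) - cols // 2) * self.dk
        return np.meshgrid(ky, kx, indexing="ij")


# ---------------------------------------------------------------------------
# LED illumination
# ---------------------------------------------------------------------------


def led_wavevector(
    led_offset: tuple[float, float], height: float, wavelength: float
) -> tuple[float, float]:
    """Transverse spatial frequency (cycles/µm) of an oblique plane wave.

    ``led_offset`` is the LED's lateral displacement from the optical axis in
    mm, ``height`` the sample-to-LED-plane distance in mm, ``wavelength`` in
    µm.  Uses the exact direction cosines ``sinθx = x / sqrt(x²+y²+h²)``
    rather than the small-angle x/h, which matters at array edges.
    """
    if height <= 0:
        raise InvalidGeometryError(f"LED height must be positive, got {height}")
    if wavelength <= 0:
        raise InvalidGeometryError(f"wavelength must be positive, got {wavelength}")
    x, y = led_offset
    norm = math.sqrt(x * x + y * y + height * height)
    return (x / norm / wavelength, y / norm / wavelength)


@dataclass(frozen=True)
class LEDArray:
    """Rectangular LED grid and the illumination wavevectors it produces.

    ``wavevectors`` holds one ``(k_x, k_y)`` pair per LED in row-major grid
    order; ``scan_order`` is the permutation in which LEDs are lit (default
    raster from the top-left).
    """

    grid_shape: tuple[int, int]
    pitch: float  # mm
    height: float  # mm
    wavelength: float  # µm
    center_offset: tuple[float, float] = (0.0, 0.0)
    wavevectors: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    scan_order: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ConfigurationError("LED grid must have at least one emitter per axis")
        if self.wavevectors is None:
            offs = self.offsets()
            wv = np.array(
                [led_wavevector((ox, oy), self.height, self.wavelength) for ox, oy in offs]
            )
            object.__setattr__(self, "wavevectors", wv)
        if self.scan_order is None:
            object.__setattr__(self, "scan_order", np.arange(rows * cols))
        sin_theta = np.hypot(*self.wavevectors.T) * self.wavelength
        if np.any(sin_theta > 1.0 + 1e-12):
            raise InvalidGeometryError("LED geometry yields |sinθ| > 1")

    def offsets(self) -> np.ndarray:
        """(N, 2) lateral LED offsets (x, y) in mm, row-major."""
        rows, cols = self.grid_shape
        ox = (np.arange(cols) - (cols - 1) / 2.0) * self.pitch + self.center_offset[0]
        oy = (np.arange(rows) - (rows - 1) / 2.0) * self.pitch + self.center_offset[1]
        gy, gx = np.meshgrid(oy, ox, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    @property
    def n_leds(self) -> int:
        return int(self.grid_shape[0] * self.grid_shape[1])

    def __len__(self) -> int:
        return self.n_leds


# ---------------------------------------------------------------------------
# coherent transfer function
# ---------------------------------------------------------------------------


def make_ctf(system: OpticalSystem, grid_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Ideal binary pupil: 1 inside the coherent cutoff disk, 0 outside."""
    if grid_shape is None:
        grid_shape = system.lores_shape
    ky, kx = system.freq_grids(grid_shape)
    extent = min((s // 2) * system.dk for s in grid_shape)
    if extent < system.cutoff:
        raise ConfigurationError(
            f"frequency extent {extent:.4g} cycles/µm of grid {grid_shape} does not "
            f"cover the coherent cutoff {system.cutoff:.4g}"
        )
    return (kx**2 + ky**2 < system.cutoff**2).astype(float)


def pupil_coords(
    system: OpticalSystem, grid_shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-disk coordinates (ρ, θ) on the pupil plus the support mask.

    ρ = |k|·λ/NA, clipped to 1 on the support boundary; θ measured from the
    k_x axis.
    """
    if grid_shape is None:
        grid_shape = system.lores_shape
    ky, kx = system.freq_grids(grid_shape)
    kr = np.hypot(kx, ky)
    support = kr < system.cutoff
    rho = np.clip(kr / system.cutoff, 0.0, 1.0)
    theta = np.arctan2(ky, kx)
    return rho, theta, support


# ---------------------------------------------------------------------------
# Zernike basis
# ---------------------------------------------------------------------------


def zernike_radial(n: int, m: int, rho) -> np.ndarray:
    """Radial Zernike polynomial R_n^m(ρ) with R_n^m(1) = 1."""
    if m < 0 or n < m:
        raise InvalidIndexError(f"require n >= m >= 0, got (n, m) = ({n}, {m})")
    if (n - m) % 2:
        raise InvalidIndexError(f"n - m must be even, got (n, m) = ({n}, {m})")
    rho = np.asarray(rho, dtype=float)
    out = np.zeros_like(rho)
    for s in range((n - m) // 2 + 1):
        coeff = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out = out + coeff * rho ** (n - 2 * s)
    return out


@dataclass(frozen=True)
class ZernikeBasis:
    """Ordered set of Zernike terms on the unit disk.

    ``terms`` is a list of ``(j, n, m)`` with signed m (m > 0 cosine,
    m < 0 sine, m = 0 rotationally symmetric).  ``normalization`` is either
    ``"unit"`` (bare polynomials, the default — the defocus term is exactly
    2ρ²−1) or ``"norm"`` (prefactor √(2(n+1)) for m ≠ 0 and √(n+1) for
    m = 0).
    """

    terms: tuple[tuple[int, int, int], ...]
    normalization: str = "unit"

    def __post_init__(self):
        if self.normalization not in ("unit", "norm"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        for j, n, m in self.terms:
            if (n - abs(m)) % 2 or n < abs(m):
                raise InvalidIndexError(f"invalid Zernike term (n={n}, m={m})")

    @classmethod
    def up_to_order(cls, n_max: int, normalization: str = "unit") -> "ZernikeBasis":
        """All terms with radial order n ≤ n_max.

        Single indices j are assigned sequentially from 1 with the cosine
        member of each (n, |m|) pair on an odd j and the sine member on an
        even j.
        """
        terms: list[tuple[int, int, int]] = []
        j = 1
        for n in range(n_max + 1):
            for m_abs in range(n % 2, n + 1, 2):
                if m_abs == 0:
                    terms.append((j, n, 0))
                    j += 1
                else:
                    first_cos = j % 2 == 1
                    pair = [(n, m_abs), (n, -m_abs)] if first_cos else [(n, -m_abs), (n, m_abs)]
                    for nn, mm in pair:
                        terms.append((j, nn, mm))
                        j += 1
        return cls(terms=tuple(terms), normalization=normalization)

    def index_of(self, n: int, m: int) -> int:
        """Position of term (n, m) in the coefficient vector."""
        for i, (_, nn, mm) in enumerate(self.terms):
            if nn == n and mm == m:
                return i
        raise InvalidIndexError(f"term (n={n}, m={m}) not in basis")

    def __len__(self) -> int:
        return len(self.terms)

    def _prefactor(self, n: int, m: int) -> float:
        if self.normalization == "unit":
            return 1.0
        return math.sqrt(2 * (n + 1)) if m != 0 else math.sqrt(n + 1)

    def evaluate_term(self, n: int, m: int, rho, theta) -> np.ndarray:
        rad = zernike_radial(n, abs(m), rho)
        if m > 0:
            ang = np.cos(m * np.asarray(theta))
        elif m < 0:
            ang = np.sin(-m * np.asarray(theta))
        else:
            ang = np.ones_like(np.asarray(rho, dtype=float))
        return self._prefactor(n, m) * rad * ang

    def design_matrix(self, rho, theta, support=None) -> np.ndarray:
        """Stack of term maps, shape (n_terms, *grid); zero outside support."""
        maps = np.stack([self.evaluate_term(n, m, rho, theta) for _, n, m in self.terms])
        if support is not None:
            maps = maps * np.asarray(support, dtype=float)
        return maps


def zernike_phase(
    basis: ZernikeBasis,
    coeffs: np.ndarray,
    rho: np.ndarray,
    theta: np.ndarray,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Pointwise Σ_i c_i Z_i(ρ, θ), zeroed outside the pupil support."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (len(basis),):
        raise DimensionMismatchError(
            f"{len(coeffs)} coefficients supplied for a {len(basis)}-term basis"
        )
    maps = basis.design_matrix(rho, theta, support)
    return np.tensordot(coeffs, maps, axes=1)


# ---------------------------------------------------------------------------
# pupil
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Pupil:
    """Aberrated pupil: real amplitude × Zernike-parameterized phase."""

    amplitude: np.ndarray
    phase: np.ndarray
    support: np.ndarray
    basis: ZernikeBasis | None = None
    zernike_coeffs: np.ndarray | None = None

    @property
    def complex_value(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape

    def with_coeffs(self, coeffs: np.ndarray, rho, theta) -> "Pupil":
        phase = zernike_phase(self.basis, coeffs, rho, theta, self.support)
        return replace(self, phase=phase, zernike_coeffs=np.asarray(coeffs, float))


def build_pupil(
    amplitude: np.ndarray,
    basis: ZernikeBasis,
    coeffs: np.ndarray,
    system: OpticalSystem,
    grid_shape: tuple[int, int] | None = None,
) -> Pupil:
    """Assemble ``c(k) · exp(i Σ c_i Z_i(k))`` on the pupil grid."""
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude < 0):
        raise ValidationError("pupil amplitude must be non-negative")
    rho, theta, support = pupil_coords(system, grid_shape or amplitude.shape)
    if amplitude.shape != rho.shape:
        raise DimensionMismatchError(
            f"amplitude shape {amplitude.shape} does not match pupil grid {rho.shape}"
        )
    phase = zernike_phase(basis, coeffs, rho, theta, support)
    return Pupil(
        amplitude=amplitude,
        phase=phase,
        support=support,
        basis=basis,
        zernike_coeffs=np.asarray(coeffs, dtype=float),
    )


def ideal_pupil(
    system: OpticalSystem,
    grid_shape: tuple[int, int] | None = None,
    basis: ZernikeBasis | None = None,
) -> Pupil:
    """Aberration-free pupil: binary CTF amplitude, zero phase."""
    if basis is None:
        basis = ZernikeBasis.up_to_order(4)
    ctf = make_ctf(system, grid_shape)
    return build_pupil(ctf, basis, np.zeros(len(basis)), system, grid_shape or ctf.shape)


# ---------------------------------------------------------------------------
# defocus calibration
# ---------------------------------------------------------------------------


def defocus_to_zernike(
    z: float,
    system: OpticalSystem,
    model: str = "paraxial",
    grid: int = 256,
) -> float:
    """Defocus Zernike coefficient (rad) for a defocus distance ``z`` (µm).

    The pupil defocus phase is least-squares projected onto the
    unit-normalized defocus polynomial 2ρ²−1 over the discretized unit disk
    (a piston term is included in the fit and discarded; it is orthogonal
    to defocus over the disk so it does not change the coefficient).

    ``model="paraxial"`` uses the quadratic phase −k0·z·(NA·ρ)²/2 (the
    projection equals −k0·z·NA²/4 in closed form); ``model="exact"`` uses
    the full defocus phase k0·z·(sqrt(1−(NA·ρ)²) − 1).  The sign flips with
    the sign of z.
    """
    if model not in ("paraxial", "exact"):
        raise ConfigurationError(f"unknown defocus model {model!r}")
    ax = np.linspace(-1.0, 1.0, grid)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    rho2 = xx**2 + yy**2
    disk = rho2 <= 1.0
    rho2 = rho2[disk]
    s = system.na**2 * rho2
    if model == "paraxial":
        phase = -0.5 * system.k0 * z * s
    else:
        phase = system.k0 * z * (np.sqrt(1.0 - s) - 1.0)
    design = np.column_stack([np.ones_like(rho2), 2.0 * rho2 - 1.0])
    coeffs, *_ = np.linalg.lstsq(design, phase, rcond=None)
    return float(coeffs[1])
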