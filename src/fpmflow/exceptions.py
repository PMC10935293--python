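"""Exception hierarchy shared across the package."""


class FPMError(Exception):
    """Base class for all fpmflow errors."""


class InvalidGeometryError(FPMError, ValueError):
    """Non-physical acquisition geometry (e.g. non-positive LED height)."""


class ConfigurationError(FPMError, ValueError):
    """Inconsistent optical/numerical configuration (e.g. cutoff beyond Nyquist)."""


class InvalidIndexError(FPMError, ValueError):
    """Invalid Zernike index pair (parity or sign violation)."""


class DimensionMismatchError(FPMError, ValueError):
    """Array shapes or lengths do not agree."""


class OutOfBandError(FPMError, ValueError):
    """A spectrum shift moves the pupil window outside the sampled grid."""


class ValidationError(FPMError, ValueError):
    """Input data violates a documented contract (negative intensity, ...)."""


class DivergenceError(FPMError, RuntimeError):
    """Optimization produced a non-finite loss."""

    def __init__(self, epoch: int, led: int | None = None):
        self.epoch = epoch
        self.led = led
        where = f"epoch {epoch}" + (f", LED {led}" if led is not None else "")
        super().__init__(f"non-finite loss encountered at {where}")
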