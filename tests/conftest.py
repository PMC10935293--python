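import numpy as np
import pytest

import fpmflow as f


@pytest.fixture(scope="session")
def system64():
    """Default desk-scale system: 64x64 hires, upsampling 4 (16x16 camera)."""
    return f.default_system()


@pytest.fixture(scope="session")
def system32():
    """Small system for fast tests: 32x32 hires, upsampling 2 (16x16 camera)."""
    return f.default_system(hires=32, upsampling=2)


@pytest.fixture(scope="session")
def leds9(system64):
    return f.default_leds((9, 9))


@pytest.fixture(scope="session")
def leds5():
    return f.default_leds((5, 5))


@pytest.fixture(scope="session")
def phantom64():
    return f.make_phantom(f.PhantomSpec(shape=(64, 64), seed=0))


@pytest.fixture(scope="session")
def case50():
    """Benchmark: 64x64 blobs/blobs phantom, 9x9 LEDs, 50 µm defocus, seed 0."""
    return f.make_benchmark_case(z=50.0, seed=0)


def centered_dft2(x, inverse=False):
    """Independent double-loop-equivalent centered unitary DFT (matrix form).

    X[u, v] = (1/sqrt(R*C)) sum_{y,x} x[y,x] e^{∓2πi[(u-cu)(y-cy)/R + (v-cv)(x-cx)/C]}
    """
    x = np.asarray(x, dtype=complex)
    sign = 1.0 if inverse else -1.0
    mats = []
    for n in x.shape:
        c = n // 2
        idx = np.arange(n) - c
        mats.append(np.exp(sign * 2j * np.pi * np.outer(idx, idx) / n) / np.sqrt(n))
    return mats[0] @ x @ mats[1].T
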