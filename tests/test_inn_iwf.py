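import numpy as np
import pytest

import fpmflow as f
from fpmflow.exceptions import ConfigurationError
from fpmflow.fourier import fft2c, ifft2c, window_bounds
from fpmflow.inn_iwf import (
    IWFParams,
    TrainConfig,
    iwf_loss,
    loss_and_gradients,
    luda_forward,
    train_inn_iwf,
    wfm_update,
    wfn_constraint,
)
from fpmflow.optics import ZernikeBasis, make_ctf, pupil_coords


def _tiny_instance(seed=0, M=8, m=4, shifts=((0, 0), (1, -1), (-2, 1))):
    """Small random problem for direct gradient checks."""
    rng = np.random.default_rng(seed)
    rows = np.empty((len(shifts), m), dtype=np.intp)
    cols = np.empty((len(shifts), m), dtype=np.intp)
    for i, (sr, sc) in enumerate(shifts):
        a, b = window_bounds((M, M), (m, m), (sr, sc))
        rows[i] = np.arange(a.start, a.stop)
        cols[i] = np.arange(b.start, b.stop)
    basis = ZernikeBasis.up_to_order(2)
    ky, kx = np.meshgrid(np.arange(m) - m // 2, np.arange(m) - m // 2, indexing="ij")
    kr = np.hypot(kx, ky)
    support = kr < 1.9
    rho = np.clip(kr / 1.9, 0, 1)
    theta = np.arctan2(ky, kx)
    zmaps = basis.design_matrix(rho, theta, support)
    params = IWFParams(
        rng.standard_normal((M, M)),
        rng.standard_normal((M, M)),
        np.abs(rng.standard_normal((m, m))),
        0.3 * rng.standard_normal(len(basis)),
    )
    y = np.abs(rng.standard_normal((len(shifts), m, m)))
    return params, y, rows, cols, zmaps, support


class TestLudaForward:
    def test_unit_pupil_on_axis_returns_spectrum_window(self, system32):
        rng = np.random.default_rng(0)
        M = system32.hires_shape[0]
        m = system32.lores_shape[0]
        obj = rng.normal(size=(M, M)) + 1j * rng.normal(size=(M, M))
        basis = ZernikeBasis.up_to_order(2)
        params = IWFParams(obj.real, obj.imag, np.ones((m, m)), np.zeros(len(basis)))
        phi_l = luda_forward(params, (0.0, 0.0), system32, basis)
        O = fft2c(obj)
        c = M // 2
        window = O[c - m // 2 : c + m // 2, c - m // 2 : c + m // 2]
        np.testing.assert_allclose(phi_l, window * (m / M), atol=1e-12)

    def test_real_imag_expansion_equals_complex_product(self, system32):
        # luda computes through the Or/Oi × Cr/Ci expansion; cross-check the
        # native complex product built from the same pupil
        rng = np.random.default_rng(1)
        M, m = system32.hires_shape[0], system32.lores_shape[0]
        obj = rng.normal(size=(M, M)) + 1j * rng.normal(size=(M, M))
        basis = ZernikeBasis.up_to_order(3)
        amp = np.abs(rng.normal(size=(m, m)))
        coeffs = 0.5 * rng.normal(size=len(basis))
        params = IWFParams(obj.real, obj.imag, amp, coeffs)
        k_n = (system32.dk * 2, -system32.dk)
        phi_l = luda_forward(params, k_n, system32, basis)

        pupil = f.build_pupil(amp, basis, coeffs, system32)
        O = fft2c(obj)
        c = M // 2
        qr, qc = 1, -2  # window center −round(k_n/dk) for (ky, kx) = (−dk, 2dk)
        window = O[
            c + qr - m // 2 : c + qr + m // 2, c + qc - m // 2 : c + qc + m // 2
        ]
        np.testing.assert_allclose(phi_l, window * pupil.complex_value * (m / M), atol=1e-12)

    def test_delta_object_yields_scaled_pupil(self, system32):
        # a point source has a flat spectrum: phi_l ∝ pupil
        M, m = system32.hires_shape[0], system32.lores_shape[0]
        obj = np.zeros((M, M), complex)
        obj[M // 2, M // 2] = 1.0
        basis = ZernikeBasis.up_to_order(2)
        rng = np.random.default_rng(2)
        amp = np.abs(rng.normal(size=(m, m)))
        coeffs = 0.4 * rng.normal(size=len(basis))
        params = IWFParams(obj.real, obj.imag, amp, coeffs)
        phi_l = luda_forward(params, (0.0, 0.0), system32, basis)
        pupil = f.build_pupil(amp, basis, coeffs, system32)
        const = fft2c(obj)[M // 2, M // 2] * (m / M)
        np.testing.assert_allclose(phi_l, pupil.complex_value * const, atol=1e-12)


class TestWFM:
    def test_zero_residual_and_zero_step_are_identities(self):
        rng = np.random.default_rng(0)
        phi = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        y = np.abs(ifft2c(phi)) ** 2
        np.testing.assert_allclose(wfm_update(phi, y, 1.3), phi, atol=1e-12)
        y2 = np.abs(rng.normal(size=(4, 4)))
        np.testing.assert_allclose(wfm_update(phi, y2, 0.0), phi, atol=1e-12)

    def test_correction_is_wirtinger_gradient_of_intensity_misfit(self):
        """The WFM correction equals −Δ/4 × the finite-difference gradient of
        Σ(|F⁻¹φ|² − y)² with respect to φ's real and imaginary parts."""
        rng = np.random.default_rng(3)
        phi = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        y = np.abs(rng.normal(size=(4, 4)))
        delta = 0.7
        corr = wfm_update(phi, y, delta) - phi

        def fobj(p):
            return np.sum((np.abs(ifft2c(p)) ** 2 - y) ** 2)

        eps = 1e-6
        fd = np.zeros((4, 4), complex)
        for idx in np.ndindex(4, 4):
            for unit in (1.0, 1.0j):
                d = np.zeros((4, 4), complex)
                d[idx] = unit * eps
                fd[idx] += unit * (fobj(phi + d) - fobj(phi - d)) / (2 * eps)
        np.testing.assert_allclose(corr, -delta / 4 * fd, atol=1e-5)


class TestWFN:
    def test_satisfied_constraint_is_identity(self):
        rng = np.random.default_rng(4)
        field = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        phi_m = fft2c(field)
        y = np.abs(field) ** 2
        np.testing.assert_allclose(wfn_constraint(phi_m, y), phi_m, atol=1e-10)

    def test_zero_intensity_gives_zero_spectrum(self):
        rng = np.random.default_rng(5)
        phi_m = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        assert np.abs(wfn_constraint(phi_m, np.zeros((8, 8)))).max() < 1e-14

    def test_output_modulus_matches_measured_intensity(self):
        rng = np.random.default_rng(6)
        phi_m = rng.normal(size=(8, 8)) + 1j * rng.normal(size=(8, 8))
        y = np.abs(rng.normal(size=(8, 8)))
        phi_h = wfn_constraint(phi_m, y)
        np.testing.assert_allclose(np.abs(ifft2c(phi_h)) ** 2, y, atol=1e-10)


class TestLoss:
    def test_equal_spectra_give_zero(self):
        x = np.ones((4, 4), complex)
        assert iwf_loss(x, x) == 0.0

    def test_constant_offset_gives_squared_modulus(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        c = 0.3 - 0.4j
        assert iwf_loss(x + c, x) == pytest.approx(abs(c) ** 2, rel=1e-12)

    def test_matches_hand_computed_mean(self):
        a = np.array([[1 + 1j, 0], [2, -1j]])
        b = np.array([[1, 1j], [0, 0]])
        # |diff|²: |1j|²=1, |−1j|²=1, |2|²=4, |−1j|²=1 → mean = 7/4
        assert iwf_loss(a, b) == pytest.approx(7 / 4)


class TestGradients:
    @pytest.mark.parametrize("mode", ["end_to_end", "detached"])
    def test_all_blocks_match_central_finite_differences(self, mode):
        params, y, rows, cols, zmaps, support = _tiny_instance()
        delta = 0.7
        _, grads = loss_and_gradients(params, y, rows, cols, zmaps, support, delta, mode)
        eps = 1e-6
        for block in ("sample_real", "sample_imag", "ctf_amplitude", "zernike_coeffs"):
            arr = getattr(params, block)
            fd = np.zeros_like(arr)
            for idx in np.ndindex(arr.shape):
                p_hi = params.copy()
                getattr(p_hi, block)[idx] += eps
                l_hi, _ = loss_and_gradients(p_hi, y, rows, cols, zmaps, support, delta, mode)
                p_lo = params.copy()
                getattr(p_lo, block)[idx] -= eps
                l_lo, _ = loss_and_gradients(p_lo, y, rows, cols, zmaps, support, delta, mode)
                fd[idx] = (l_hi - l_lo) / (2 * eps)
            scale = max(np.abs(fd).max(), 1e-12)
            assert np.abs(grads[block] - fd).max() / scale < 1e-4, block


class TestTraining:
    def test_zero_learning_rates_leave_parameters_unchanged(self, case50):
        stack, sys_ = case50.stack, case50.system
        basis = case50.pupil.basis
        init = IWFParams(
            case50.ground_truth.real,
            case50.ground_truth.imag,
            make_ctf(sys_),
            np.zeros(len(basis)),
        )
        cfg = TrainConfig(epochs=2, lr_sample=0.0, lr_pupil=0.0)
        res = train_inn_iwf(stack, sys_, init=init, config=cfg, basis=basis)
        np.testing.assert_allclose(res.params.object_values, case50.ground_truth.values, atol=1e-12)
        np.testing.assert_array_equal(res.params.zernike_coeffs, np.zeros(len(basis)))

    def test_truth_is_fixed_point_with_zero_loss(self, case50):
        stack, sys_ = case50.stack, case50.system
        basis = case50.pupil.basis
        init = IWFParams(
            case50.ground_truth.real,
            case50.ground_truth.imag,
            make_ctf(sys_),
            case50.pupil.zernike_coeffs.copy(),
        )
        res = train_inn_iwf(stack, sys_, init=init, config=TrainConfig(epochs=5), basis=basis)
        assert res.loss_trace.max() < 1e-20
        assert np.abs(res.params.object_values - case50.ground_truth.values).max() < 1e-8
        assert np.abs(res.params.zernike_coeffs - case50.pupil.zernike_coeffs).max() < 1e-8

    def test_au_phases_only_touch_their_own_blocks(self, case50):
        """Sample epochs leave the pupil bit-identical and vice versa."""
        stack, sys_ = case50.stack, case50.system
        basis = case50.pupil.basis
        from fpmflow.inn_iwf import default_init

        init = default_init(stack, sys_, basis)

        cfg_s = TrainConfig(epochs=1, au_schedule=("sample",))
        res_s = train_inn_iwf(stack, sys_, config=cfg_s, basis=basis)
        np.testing.assert_array_equal(res_s.params.ctf_amplitude, init.ctf_amplitude)
        np.testing.assert_array_equal(res_s.params.zernike_coeffs, init.zernike_coeffs)
        assert not np.array_equal(res_s.params.sample_real, init.sample_real)

        cfg_p = TrainConfig(epochs=1, au_schedule=("pupil",))
        res_p = train_inn_iwf(stack, sys_, config=cfg_p, basis=basis)
        np.testing.assert_array_equal(res_p.params.sample_real, init.sample_real)
        np.testing.assert_array_equal(res_p.params.sample_imag, init.sample_imag)
        assert not np.array_equal(res_p.params.zernike_coeffs, init.zernike_coeffs)

    def test_loss_non_increasing_at_small_learning_rates(self, case50):
        cfg = TrainConfig(epochs=20, lr_sample=10.0, lr_pupil=1.0)
        res = train_inn_iwf(case50.stack, case50.system, config=cfg, basis=case50.pupil.basis)
        lt = res.loss_trace
        assert np.all(np.diff(lt) <= 1e-6 * lt[:-1])

    def test_invalid_epochs_rejected(self):
        with pytest.raises(ConfigurationError):
            TrainConfig(epochs=0)
        with pytest.raises(ConfigurationError):
            TrainConfig(au_schedule=("sample", "both"))
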