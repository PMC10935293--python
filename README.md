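# fpmflow

Fourier ptychographic microscopy (FPM) simulation and aberration-correcting
reconstruction in pure scientific Python.

FPM replaces a microscope's condenser with an LED array: each LED illuminates
the sample with an oblique plane wave of transverse frequency
**k**ₙ = (sin θₓ/λ, sin θᵧ/λ), so the camera records a low-resolution
intensity image `Iₙ(r) = |F⁻¹{ C(k) · O(k − kₙ) }|²`, a pupil-filtered window
of the object spectrum `O(k)`. Stitching the windows of many LEDs synthesizes
an aperture far larger than the objective NA — but any aberration of the
coherent transfer function (CTF) `C(k)`, in practice dominated by defocus,
corrupts every window and the stitched result.

This package provides:

* a **forward simulator** of the full acquisition (LED geometry, pupil
  low-pass, Fourier-domain detector decimation, optional shot/read noise);
* the **classical alternating-projection reconstruction** (Fourier-magnitude
  replacement over all LED windows), used as the uncorrected baseline;
* an **aberration-correcting reconstruction** that treats the complex object
  (real/imaginary high-resolution maps) and the pupil (CTF amplitude map +
  Zernike phase coefficients `∠C(k) = Σᵢ cᵢ Zᵢ(k)`) as learnable parameters of
  a differentiable forward model. Each LED pass applies one Wirtinger-Flow
  gradient step on the intensity misfit `‖ |F⁻¹φₗ|² − y ‖²`, re-imposes the
  measured modulus `√y`, and minimizes the spectral MSE between pre- and
  post-update spectra by plain gradient descent with an *alternating update*
  (AU) schedule: object epochs and pupil epochs use separate learning rates.
  Gradients are hand-derived Wirtinger adjoints (no autodiff framework),
  validated against central finite differences;
* **Zernike optics utilities**, including the defocus calibration: a defocus
  plane at distance *z* maps to the unit-normalized defocus coefficient
  `c₂₀ ≈ −k₀ z NA²/4` (least-squares projection of the paraxial pupil phase
  onto 2ρ²−1). For z = 50 µm, NA = 0.1, λ = 532 nm this gives **−1.48 rad**;
* **PSNR/SSIM metrics** and a synthetic benchmark generator (complex
  phantoms with independent amplitude/phase patterns, defocused pupils at
  25/50/75 µm, reproducible acquisition stacks).

## Worked example

```python
import fpmflow as fpm
from fpmflow.inn_iwf import TrainConfig, train_inn_iwf
from fpmflow.classic_recon import reconstruct_classic
from fpmflow.optics import ideal_pupil

# simulate a 50 µm defocus-aberrated acquisition (9×9 LEDs, 64×64 phantom)
case = fpm.make_benchmark_case(z=50.0, seed=0)
z20_true = case.pupil.zernike_coeffs[case.pupil.basis.index_of(2, 0)]

# uncorrected baseline: alternating projections with the ideal CTF
obj_c, _ = reconstruct_classic(case.stack, case.system,
                               ideal_pupil(case.system), n_iters=50)
base = fpm.compare_complex(case.ground_truth.values, obj_c.values)

# aberration-correcting reconstruction
res = train_inn_iwf(case.stack, case.system,
                    config=TrainConfig(epochs=5000), basis=case.pupil.basis)
z20 = res.params.zernike_coeffs[case.pupil.basis.index_of(2, 0)]
corr = fpm.compare_complex(case.ground_truth.values, res.object_estimate.values)
```

prints (via the accompanying formatting):

```
stack: 81 images of (16, 16)
injected defocus coefficient: -1.476 rad
recovered defocus coefficient: -1.476 rad
amplitude PSNR  uncorrected 13.78 dB -> corrected 19.88 dB
amplitude SSIM  uncorrected 0.220 -> corrected 0.723
```

The trained model recovers the injected defocus Zernike coefficient
essentially exactly and improves the amplitude reconstruction by ~6 dB over
the uncorrected baseline; with the aberration absorbed into the recovered
pupil, the remaining error is the synthetic-aperture coverage limit.

The same pipeline is scriptable from the shell:

```bash
fpmflow simulate --defocus-um 50 --leds 9x9 --seed 0 --out run/
fpmflow reconstruct --stack run/stack.tif --method inn_iwf --out run/recon
fpmflow evaluate --truth run/ground_truth --recon run/recon --out run/metrics.csv
fpmflow calibrate-defocus --z-um 50        # -> -1.476312
```

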