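# Methods

## Forward model

The object is a complex transmission function `o(r)` sampled on an `M × M`
high-resolution grid with object-plane pixel `p` (µm). All transforms are
unitary FFTs in a *centered* layout (zero frequency at index `M//2`), so
Parseval's identity holds exactly and every adjoint of a transform is its
inverse. Spatial frequencies are kept in cycles/µm throughout; the coherent
cutoff of the objective is `NA/λ` and the angular wavenumber `k₀ = 2π/λ`
appears only in phase calculations (defocus). The frequency sampling is
`Δk = 1/(M·p)`; the camera grid (`m = M/u` pixels) shares it, so detector
downsampling is implemented as Fourier-domain decimation: the pupil window
is the central `m × m` crop of the shifted high-resolution spectrum. The
decimation carries the value-preserving factor `m/M` so a unit-amplitude
object produces unit camera intensity.

An LED at lateral offset `(x, y)` mm and height `h` mm below the sample
illuminates with transverse frequency `(x, y)/(λ·√(x²+y²+h²))` — exact
direction cosines rather than the small-angle `x/h`, which differ by ~2% at
the array edge (28 mm offset at 100 mm height). Illumination shifts are
quantized to the nearest integer frequency pixel so reconstruction
write-backs operate on aligned windows; sub-pixel residuals are recorded on
the stack for diagnostics. At the default geometry the largest residual-
induced frequency error is below `Δk/2 ≈ 0.036` cycles/µm.

The simulated camera image for LED *n* is
`Iₙ = | F⁻¹{ C(k) · O(k − kₙ) }|²` on the `m × m` grid. Optional noise
(Poisson shot noise at a configurable photon budget plus Gaussian read
noise) is off by default; the benchmark acquisitions are noiseless.

## Pupil model

The pupil is `C(k) = c(k) · exp(i Σᵢ cᵢ Zᵢ(k))`: a free non-negative
amplitude map times a Zernike-parameterized phase. Zernike terms are
addressed by radial order *n* and azimuthal frequency *m* (`m > 0` cosine,
`m < 0` sine), with a sequential single index kept only for serialization
(odd index = cosine member, even = sine member of each pair). Two
normalizations are available: `unit` (bare polynomials; the defocus term is
exactly `2ρ² − 1`) — the default — and `norm` (prefactors `√(2(n+1))` for
`m ≠ 0`, `√(n+1)` for `m = 0`). The unit convention is the one under which
the 50 µm defocus plane at NA 0.1, λ 532 nm calibrates to ≈ −1.48 rad, the
package's reference calibration value. Pupil-disk coordinates map
`|k| = NA/λ` to `ρ = 1`, clipped at the support boundary; the phase is zero
outside the support by convention (the amplitude map is a whole learnable
map and is not masked).

`defocus_to_zernike` computes the defocus coefficient by numerical
least-squares on a discretized unit disk (piston included in the fit and
discarded; it is orthogonal to defocus over the disk). Two defocus phase
models are provided because the sign/parameterization convention of the
calibration is not fixed by first principles: `paraxial`
(`−k₀ z (NA·ρ)²/2`, whose projection is `−k₀ z NA²/4` in closed form) and
`exact` (`k₀ z (√(1−(NA·ρ)²) − 1)`). At NA 0.1 they agree within 0.3%.

## Classical baseline

The uncorrected arm is plain alternating projections: per LED, predict the
camera field from the current spectrum estimate, replace its modulus by the
measured `√I` (keeping phase; zero-modulus pixels keep phase 0), transform
back and write the patch into the shifted spectrum window inside the pupil
support, dividing by the pupil where it has modulus. No ePIE step size or
conjugate-pupil weighting is applied — this arm is deliberately the plain
Gerchberg–Saxton-style stitcher that has no way to fix an unmodeled pupil
phase. Initialization is the Fourier-upsampled square root of the
center-LED image (an all-ones init is available); LEDs are processed in
raster scan order; stopping is a fixed sweep count (default 50) or relative
spectrum change below 1e−6.

## Aberration-correcting reconstruction

Learnable parameters: the object split into real and imaginary maps
(`M × M` each), the CTF amplitude map (`m × m`, kept non-negative by
projection after each step) and the Zernike phase coefficients (all terms
with `n ≤ 4` by default, 15 coefficients). Per LED the chain is

```
φ_l = O window(k_n) ⊙ C                      (forward unit)
a   = F⁻¹ φ_l
φ_m = φ_l − Δ·F{(|a|² − y) ⊙ a}              (one Wirtinger-Flow step)
φ_h = F{ √y · exp(i ∠F⁻¹ φ_m) }              (measured-modulus constraint)
loss = mean |φ_h − φ_l|²                     (spectral MSE, mean over LEDs)
```

with `y` the measured intensity on the pupil-window grid (images coarser
than that grid are upsampled by Fourier zero-padding of `√I` and
re-squaring; at the native camera grid this is the identity, which is what
makes noiseless self-consistency exact).

**A structural identity worth knowing.** Because the transforms are
unitary, `F⁻¹φ_m = a·(1 − Δ·(|a|² − y))` is pointwise collinear with `a`, so
the phase entering the modulus constraint equals the phase of `a` (mod π
where `Δ·(|a|²−y) > 1`). The loss therefore reduces almost everywhere to
the classical amplitude misfit `mean(√y − |a|)²` and is locally independent
of Δ, and the gradient contribution through the φ_h branch vanishes:
end-to-end differentiation and treating φ_h as a detached target give
identical gradients (both modes are implemented and finite-difference
checked; `mode="detached"` exists for ablation). Δ is retained as the
documented step parameter of the update chain, with default 1 after the
measured stack is normalized to unit mean intensity.

Gradients are hand-derived Wirtinger adjoints (convention: propagate
`∂L/∂w̄`; a real leaf entering as `w = x` or `w = ix` receives `2·Re` or
`2·Im` of it). The angle/modulus-replacement step is differentiable almost
everywhere; zero-modulus pixels get zero gradient. All four parameter
blocks match central finite differences to better than 1e−4 relative on
small random instances (tested).

Training is plain gradient descent with the alternating-update schedule:
epochs cycle through `("sample", "pupil")`, each phase updating only its
own blocks with its own learning rate, so held blocks are bit-identical
across foreign epochs. The intensity normalization is folded into the
forward scale constant (not into the object parameters), which keeps the
object in the caller's units and preserves that bit-identity. The full LED
batch is processed per epoch, vectorized over LEDs.

### Learning rates and epochs

With a mean-reduced loss over `N·m²` pixels and unit-mean intensities,
per-pixel gradients are of order `1/(N·m²)`, so usable learning rates are
large: defaults `lr_sample = 100`, `lr_pupil = 10`, 2000 epochs (the
acceptance benchmarks use 5000), chosen from a convergence study on the
standard benchmark — at those rates the 50 µm defocus coefficient is
recovered to ≪1% and the loss drops ~6 orders of magnitude; at ~3× larger
rates optimization destabilizes. The 10:1 ratio between object and pupil
rates is what the alternating-update scheme exists to allow. Note the loss
trace at the fast defaults *oscillates between AU phases* (each phase
partially undoes the other early in training) while trending down; at
small rates (e.g. 10/1) it is strictly non-increasing, which is the regime
the monotonicity test exercises.

## Metrics

PSNR is `−10·log₁₀ MSE` on unit-range images (peak 1; identical images give
+∞). SSIM has a `global` mode (single luminance/contrast/structure
statistic from whole-image moments, population covariance) and a `windowed`
mode (uniform 7×7 sliding windows, sample-covariance normalization, mean
over the valid region; matches the standard library implementation to
1e−6). Defaults `C₁ = 1e−4`, `C₂ = 9e−4` (k₁ = 0.01, k₂ = 0.03, L = 1); a
strictly-equal-constants variant is available via the arguments.
Reconstructions are compared after min-max normalizing amplitudes and
affinely aligning phases to the reference (a global phase offset/scale is
unidentifiable in FPM).

## Synthetic benchmark

Geometry defaults emulate the reference acquisition hardware: λ = 532 nm,
NA = 0.1, 3.45 µm camera pixels, LED plane 100 mm below the sample. The
objective magnification and LED pitch are not determined by that hardware
description; the package assumes the canonical 4×/0.1 FPM objective
(0.8625 µm object-plane camera pixel) and 4 mm pitch, both configurable.
Desk scale is a 64×64 high-resolution grid at upsampling 4 with a 9×9 LED
grid (81 images, synthetic NA ≈ 0.32); the full 15×15 scan (225 images) is
available and used for the acquisition-count check.

Phantoms combine independent amplitude and phase patterns (checker /
smoothed random blobs / text-like stripes / user-supplied image file) —
amplitude in [0.5, 1], phase in [−π/2, π/2] by default, deterministic per
seed. The default benchmark phantom uses smooth "blobs" for both channels:
the benchmark isolates *aberration-induced* error, so most of the complex
field's energy must lie inside the synthetic aperture (a broadband phase
pattern caps every method's amplitude PSNR near 12.6 dB at desk scale,
drowning the effect under the coverage limit). Striped and checkered
patterns remain available for resolution-oriented experiments.

What passing the synthetic benchmarks does **not** show: robustness to
detector noise (benchmarks are noiseless; the noise model exists but is
off), LED position errors or intensity miscalibration (not modeled),
partially coherent illumination, or performance on real tissue imagery with
its broadband spectra and model mismatch. Absolute PSNR values at desk
scale are dominated by synthetic-aperture coverage of the phantom and are
not comparable to values obtained at other scales or with other images.

## Numerical choices and degenerate inputs

* Fixed points are exact by construction: a noiseless stack generated from
  `(O*, C*)` is bit-stable under classical sweeps with `C*` and drift-free
  (<1e−8 over 5 epochs) under training initialized at `(O*, C*)`.
* Zero-modulus pixels: phase 0 by convention in magnitude replacement,
  zero gradient in training; stabilizing constants keep SSIM finite on
  constant images; PSNR of identical images is the +∞ sentinel.
* Out-of-band LED windows raise a descriptive error naming the LED.
* All stochastic paths (noise, any randomized init) take explicit seeds;
  defaults are deterministic.

## Known limitations

* Defocus-plane PSNR monotonicity (25 ≥ 50 ≥ 75 µm) is a direction-only
  trend; on some phantom seeds the 75 µm case rebounds slightly because the
  larger aberration is still fully recoverable while the PSNR differences
  near the coverage ceiling are small.
* Plain gradient descent needs thousands of (cheap, vectorized) epochs;
  momentum/adaptive optimizers were deliberately not made the default.
* The pupil phase is only identifiable up to the constant (piston) term,
  and only within the aperture actually sampled by the LED set.
* Sub-pixel illumination components are quantized away rather than modeled.
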