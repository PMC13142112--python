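# Methods

This note documents the models, numerical choices and study protocol
implemented by `msfgan_pat`, in the package's own terms.

## Problem setting

Circular-array photoacoustic tomography (PAT) measures time-resolved
pressure traces `y` on a ring of ultrasound elements surrounding the
sample.  With a discrete linear forward operator `A` and noise `n`,

    y = A x + n,

where `x` is the initial pressure image.  Sparse-view acquisition keeps
only a uniform subset of elements (e.g. 64 or 32 of 256), accelerating
imaging at the price of streak artifacts in the delay-and-sum (DAS)
reconstruction `x0 = R_D(y)`.  The package implements the forward
model, DAS, and an adversarially trained network `G` that maps `x0` to
an artifact-suppressed image, plus the evaluation harness (PSNR, SSIM,
FWHM resolution, comparison arithmetic).

## Forward operator

`A` is factored as `H ∘ D_t ∘ S`:

* `S` — arc integrals (the 2-D spherical mean): for element position
  `r_e` and time `t_k = k·dt`, the integral of `x` over the circle of
  radius `c·t_k` centered at `r_e`, evaluated by bilinear sampling at
  an arc quadrature step of `0.5·dx` and materialized once per
  (geometry, grid) as a sparse matrix per element.  Sampling angles are
  tied to each element's own frame, which makes the discrete operator
  exactly equivariant under rotations by the inter-element angle.
* `D_t` — centered finite-difference time derivative (the N-wave
  signature of a pressure release).
* `H` — convolution with a Gaussian-modulated sinusoid whose −6 dB
  fractional bandwidth matches the transducer specification (default
  80%).  The kernel is symmetric, so `H` is self-adjoint.

Each factor has an exact transpose, so the adjoint is exact as a linear
map; the inner-product identity `⟨Ax, y⟩ = ⟨x, Aᵀy⟩` holds to ~1e-15
relative and is the operator-correctness oracle in the tests.  Grid
convention: pixel centers, origin at the grid center, x rightward,
y upward, element 0 on the +x axis, time starts at 0 with `c·dt = dx`.

Discretization caveat: the pixelized image is rotation-invariant only
under the grid's 90° symmetries, so "identical traces for a centered
disc" holds exactly on that subgroup and to within interpolation error
(≈1–3% for a band-limited disc) at generic angles.

Heterogeneous sound speed, acoustic attenuation, element directivity
and 3-D detection are out of scope; 3-D data are handled as stacks of
independent 2-D slices.

## DAS and preprocessing

DAS sums each kept trace at the time-of-flight delay `|r − r_e|/c`
with linear interpolation and no apodization; delays outside the
recorded window contribute zero, so the map is linear in the sinogram.
Optional preprocessing per trace: zero-phase 4th-order Butterworth
band-pass, and the Hilbert envelope.  Images are min-max normalized to
[0, 1] (constant images map to zeros) before any metric.

Two envelope stages exist and they are not interchangeable.  Per-trace
envelope detection (before beamforming) is available but off by
default: summing non-negative envelopes destroys phase coherence and
buries the image under a smooth background pedestal shared by all view
counts.  The study protocol instead beamforms the bipolar RF and takes
the *image-domain* envelope (`image_envelope`: rectification by
default, axis-wise Hilbert magnitude as an alternative), which leaves
bright structures on a dark background — the display form of PAT
reconstructions, and the stage at which the in vivo processing chain
applies its Hilbert transform.  Point-source localization is measured
on envelope images for the same reason — the absolute peak of a raw
bipolar wavelet sits a quarter period off the true arrival, which is
physics, not reconstruction error.

## Networks

Both networks are built on a small reverse-mode autodiff engine
(`msfgan_pat.nn`) written on numpy with numba-compiled convolution
loops.  Every primitive's vector-Jacobian product is itself expressed
through primitives, so gradients can be differentiated again — the
discriminator gradient penalties require exactly that.  Features are
stored channel-leading (C, N, H, W), which lets every convolution run
as one BLAS matmul against the im2col gather with no layout copies.

**Generator.**  Shallow 3×3 conv + PReLU encoding; in the default
`same` scale mode two stride-2 conv+PReLU reducers (mirroring the two
×2 sub-pixel units so input and output grids match); `B` feature-
enhance blocks; a trunk conv+BN with a global skip from the reduced
head features; two sub-pixel units (conv to 4C, pixel shuffle r=2,
PReLU); a final 3×3 conv to one channel.  Each feature-enhance block
applies the pyramid squeeze attention (PSA) module — 1×1 conv+BN+ReLU
remap, four parallel conv branches with kernels {3,5,7,9} producing
`Cb = C/4` channels each, a squeeze-and-excitation gate per branch
(reduction 4, ReLU bottleneck, sigmoid output), a per-channel softmax
across the four scales, concatenation, 1×1 conv+BN+ReLU back to `C`,
plus an inner residual — followed by conv+BN and the outer residual
`Fe = F0 + Fr`.  Zeroing the fusion / post-PSA convolutions yields
exact pass-through, which the tests assert.  Convolutions feeding a
BatchNorm carry no bias (a bias there is exactly unidentifiable).
Defaults C=64, B=8; the desk-scale protocol uses C=32, B=4.

**Discriminator.**  A U-Net that scores every pixel: stride-2
spectral-normalized conv + LeakyReLU(0.2) encoder (widths
64/128/256 by default), bilinear-×2 + SN-conv + LeakyReLU decoder, a
final 1×1 conv to a one-channel realness map at input resolution.
Each skip is gated by a channel attention module (CAM): global average
and max pooled descriptors pass a shared two-layer 1×1-conv gate
(reduction 8) and the sigmoid attention rescales the encoder feature
before addition.  Spectral normalization tracks the leading singular
pair with one power-iteration step per training forward; the
normalized weights stay within 1% of unit spectral norm.

## Losses

Discriminator: `L_D = L_Rp + λ1·R1 + λ2·R2` with the relativistic
pairing `L_Rp = E[−log σ(D(x_f) − D(x̂))]` computed per pixel of the
realness maps (a switch reduces to scalar pairing), and gradient
penalties `R1 = (γ1/2)·E‖∇_x D(x_f)‖²`, `R2 = (γ2/2)·E‖∇_x D(x̂)‖²`
with `x̂` detached from the generator.  Defaults γ1=0.5, γ2=1, λ1=1,
λ2=0.8, so the effective penalty weights are 0.25 and 0.4.  Generator:
the role-swapped pairing `E[−log σ(D(x̂) − D(x_f))]`, optionally plus a
pixel-fidelity term; `total_losses` keeps that term off by default,
while the trainer enables an L1 term because purely adversarial
training of a reconstructor on a few hundred images is
under-constrained.  Since the discriminator scores samples
independently, the trainer evaluates both penalties in a single
differentiation pass over the stacked real/generated batch (tested
equal to the separate evaluations).

## Training protocol

Alternating updates, one discriminator step then one generator step
per batch; Adam (β1=0.9, β2=0.999, ε=1e-8); learning rate halved after
`halving_epoch` (defaults 1e-4 and 150 of 200 epochs, batch 8,
geometric ×4 augmentation); validation PSNR after every epoch; the
checkpoint with the best validation score is kept (ties to the
earliest epoch).  Everything is seeded and single-thread
deterministic.  Non-finite losses abort with the last loss report.

## The desk-scale study protocol

Full-scale training (500 phantoms at 256×256, 256 elements, 200
epochs) is beyond a single CPU, so the end-to-end properties are
exercised on a proportionally scaled problem (`msfgan_pat.protocols`):
200 random-walk vascular phantoms on a 64×64 grid (dx = 0.1 mm), split
8:1:1; a 64-element ring at 2.5 MHz / 80% bandwidth (the coarser grid
cannot support the 5.5 MHz band at 15 MS/s sampling); bipolar DAS
followed by the image-domain envelope for both the full-view targets
and the 16-view uniform-subset inputs (the same 4× subsampling as
256→64); generator C=32/B=4; discriminator widths (8, 16, 32);
30 epochs at batch size 2 (the fixed epoch budget makes update count
the scarce resource, so a small batch is traded for 2400 updates),
lr 1e-3 halved after 3/4 of training, no augmentation; loss weights as
above with pixel L1 weight 100.  At seed 1 this raises held-out PSNR
from 13.7 dB (sparse input) to 16.8 dB and doubles SSIM.  The
synthetic vessels emulate branching vascular trees with multiscale
radii; they do not emulate organ backgrounds, acoustic heterogeneity,
or measurement noise, so passing results demonstrate correct and
effective artifact removal under the stated acquisition model rather
than in-vivo performance.

## Evaluation

PSNR = 10·log10(R²/MSE) with data range fixed at 1.0 on normalized
images and identical pairs capped at 99 dB.  DAS images (arbitrary
scale) are min-max normalized; network outputs, trained toward [0,1]
targets, are clipped instead — per-image rescaling would let a single
outlier pixel compress the whole image.  SSIM uses the standard
Gaussian 11×11 / σ=1.5 window, K1=0.01, K2=0.03 (scikit-image);
aggregation as mean ± sample (n−1) standard deviation; pairwise
differences and relative gains 100·(a−b)/b rounded to 3 decimals.
FWHM of a 1-D profile by linear interpolation of the half-maximum
crossings.  The theoretical axial resolution helper is c/(2·Δf) with
Δf the fractional bandwidth times the center frequency and
c = 1540 m/s (soft-tissue convention), giving 175 μm at 5.5 MHz and
385 μm at 2.5 MHz at 80% bandwidth.

## Known limitations

* The forward model is a band-limited ray/arc model, not a full-wave
  solver; it shares the geometry and bandwidth of the physical system
  but not finite-element-size or dispersion effects.
* The adversarial objective adds realism pressure but the quantitative
  gains of the scaled protocol are carried mainly by the fidelity
  term.  As a consequence, single-module ablation effects (PSA off,
  CAM off, penalties off) measure 0.01–0.15 dB at desk scale — below
  run-to-run noise — and their expected ordering does not reliably
  materialize; distinguishing the modules requires the full-scale
  regime (larger images, hundreds of epochs, adversarially dominated
  training).
* BatchNorm statistics are estimated from small batches; inference
  uses running averages, so train/eval outputs differ slightly.
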