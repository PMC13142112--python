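# msfgan-pat

Sparse-view photoacoustic tomography (PAT) reconstruction on synthetic
phantoms: a circular-array acoustic forward model with an exact
adjoint, delay-and-sum (DAS) beamforming, and an adversarially trained
artifact-removal network with pyramid squeeze attention, a
channel-attention U-Net discriminator, and a dual-gradient-regularized
relativistic loss.

## Who this is for

PAT imaging is acquired on a ring of ultrasound elements; keeping only
a uniform subset of elements (64 or 32 of 256) accelerates acquisition
but leaves streak artifacts in the DAS image.  This package is for
researchers who want a self-contained, CPU-only re-implementation of
that reconstruction chain — forward model `y = Ax + n`, beamforming
`x0 = R_D(y)`, and a learned mapping `x̂ = G(x0)` that suppresses the
artifacts — together with the evaluation harness used to compare
reconstruction methods (PSNR/SSIM with mean ± std aggregation,
relative-gain arithmetic, FWHM resolution).

## The model in brief

* **Forward operator** `A = H ∘ D_t ∘ S`: arc integrals of the initial
  pressure over circles `|r − r_e| = c t` (the 2-D spherical mean),
  a centered time derivative, and a Gaussian-modulated sinusoid
  impulse response at the transducer's center frequency and −6 dB
  fractional bandwidth.  The adjoint is exact: `⟨Ax, y⟩ = ⟨x, Aᵀy⟩`
  to machine precision.
* **DAS**: `x0(r) = Σ_e y_e(|r − r_e|/c)` with linear interpolation,
  optional band-pass and Hilbert-envelope preprocessing.
* **Generator** `G`: shallow conv+PReLU encoding, B pyramid-squeeze-
  attention blocks (four parallel kernels 3/5/7/9, per-branch
  squeeze-excitation gates, softmax across scales, inner and outer
  residuals), sub-pixel upsampling, trained with the relativistic
  adversarial loss `−log σ(D(x̂) − D(x_f))` plus an L1 fidelity term.
* **Discriminator** `D`: spectrally normalized U-Net with channel-
  attention skip gates, returning a per-pixel realness map; trained
  with `L_Rp + λ1 R1 + λ2 R2`, the R1/R2 gradient penalties evaluated
  at full-view and generated images (γ1=0.5, γ2=1, λ1=1, λ2=0.8).

Everything — including the reverse-mode autodiff engine behind the
networks — runs on numpy/numba; see `docs/methods.md` for details and
design rationale.

## Worked example

```bash
# 200 vascular phantoms on a 64x64 grid, split 8:1:1
msfgan-pat simulate --n 200 --grid 64 --dx 1e-4 --seed 1 --out data.h5

# project with a 64-element ring at 2.5 MHz and beamform 16-view DAS
msfgan-pat project --in data.h5 --views 64 --fc 2.5e6
msfgan-pat das --in data.h5 --views 16 --out recon16.h5

# train the desk-scale protocol and report test metrics
msfgan-pat train --scaled --seed 1 --out runs/demo
cat runs/demo/metrics.json
```

The training command prints one line per epoch (losses, learning rate,
validation PSNR) and writes `metrics.json` with the held-out
comparison of the sparse DAS input and the network output against the
full-view DAS targets.  With seed 1 it prints:

```json
{
  "val_psnr": 16.90,
  "das_psnr": 13.698,
  "das_ssim": 0.0736,
  "net_psnr": 16.837,
  "net_ssim": 0.1471
}
```

Reading: the 16-view DAS input scores 13.70 dB PSNR / 0.074 SSIM
against the 64-view targets on the 20 held-out phantoms; the trained
network raises that to 16.84 dB / 0.147 — a +3.1 dB artifact-removal
gain with doubled structural similarity.  The library API
(`msfgan_pat.protocols.run_scaled_protocol`) returns the same numbers
programmatically.  `msfgan-pat ablate` trains the single-ablation
variants (PSA off, CAM-gated skips off, gradient penalties off) on the
same data and seed, and `msfgan-pat resolution --fc 5.5e6` prints the
theoretical axial resolution (175 um at 5.5 MHz, 385 um at 2.5 MHz).

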