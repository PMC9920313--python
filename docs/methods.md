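# Methods

This note records the models, conventions and design choices behind
`freqcycle`, in the order a reader would meet them in the pipeline.

## Volumes and preprocessing

A `Volume3D` stores intensities in array index order (z, y, x) with spacing
and origin in (x, y, z) millimetres — the convention of the NIfTI/NRRD/
MetaImage headers it is read from. Intensities are either Hounsfield units
(HU) or normalized to [-1, 1]; the `scale_tag` makes the scale explicit and
is validated on construction.

- **Resampling** uses linear interpolation for intensity volumes and
  nearest-neighbour for masks (labels must not bleed). Output shape is
  round(shape x spacing / target), at least 1 per axis; resampling to the
  volume's own spacing is short-circuited to the identity so it is
  voxel-exact.
- **Body masking** (the derivation is a package choice): threshold at
  -300 HU, keep the largest 26-connected component, fill holes per axial
  slice so the lungs stay inside the mask. The threshold is configurable.
  Voxels outside the mask are set to -1000 HU (air), a physically neutral
  background.
- **Field-of-view truncation** crops (and air-pads) a CT so its physical
  extent matches a CBCT's, with all arithmetic in millimetres
  (origin + spacing x shape); extents agree within half a voxel per axis.
- **Intensity windows.** Network inputs are clipped to [-1000, 2000] HU and
  mapped linearly onto [-1, 1], because the generator ends in tanh;
  evaluation clips to [0, 3000] HU (the reference protocol). Both windows
  are configuration keys, and every metric report records the clip range
  and mask convention it used.

## The frequency representation and structure loss

The representation is tanh(|fftshift(DFT(I))|) with the DFT scaled by
1/sqrt(LMN). Two scaling conventions are exposed:

- `ortho` (default): 1/sqrt(LMN), the unitary DFT. This is the convention
  under which Parseval's identity holds exactly, which the test suite
  verifies to 1e-6 on a thousand random volumes.
- `forward`: 1/(LMN), for strict agreement with the plainly normalised
  transform.

The full complex DFT is used (not the real-input half-spectrum) so the
centred magnitude volume has the input's shape and the shift-insensitivity
property is exact. Zero frequency sits at index floor(n/2) per axis.
tanh is applied to the magnitude only; phase is discarded entirely. Values
are in [0, 1) mathematically; in float64, magnitudes above ~19 saturate to
exactly 1.0, where the loss gradient is correspondingly zero.

The distance between two volumes is the elementwise L1 (or squared L2)
difference of their representations, summed over all frequency bins by
default (`reduction="sum"`); a `mean` reduction is exposed because summed
losses scale with patch size. The loss is symmetric, non-negative, zero on
circular shifts, and differentiable — the backward pass uses the adjoint
DFT (the inverse unitary transform), and is finite even at zero-magnitude
bins, where the direction factor is defined as 0.

## Objective

    L = L_adv(G, D_Y) + L_adv(F, D_X)
        + lambda_A cycle_A + lambda_B cycle_B
        + lambda_fA d(G(x), x) + lambda_fB d(F(y), y)

Defaults: lambda_A = lambda_B = 5 and lambda_fA = lambda_fB = 5. With the
frequency lambdas at zero the objective is bit-identical to the plain
CycleGAN. Two adversarial variants are implemented: least squares (default,
the stable choice in the CycleGAN lineage; raw discriminator scores) and
the log-form vanilla objective (non-saturating generator term; scores are
squashed through a sigmoid first). No identity loss is included. The
structure loss is applied symmetrically on both mappings and is pluggable
(`none`, `frequency_l1`, `frequency_l2`); a descriptor-based loss could be
added behind the same interface.

## Networks

The generator is a 3D VNet: an input block (kernel-5 convolution, instance
norm, PReLU), four down stages with (1, 2, 3, 2) convolutional blocks each
ending in a stride-2 convolution, four up stages with (2, 2, 1, 1) blocks
fed by kernel-equals-stride transposed convolutions and UNet-style skip
concatenation, and an output block whose final convolution is followed by
tanh. Striding along z is disabled in the last two down stages, so a
16-slice patch remains admissible (z halves at most twice: 16 -> 8 -> 4)
while in-plane dimensions halve at all four stages (320 -> 20). Kernel size
is 3 everywhere except the input block. Channel width doubles per stage
from a configurable `base_filters` (default 16; the published description
fixes the block pattern but not the widths, so width is a free knob).

The discriminator is a 3D PatchGAN: strided convolutions (z-striding only
in the first layer) with instance norm and LeakyReLU(0.2), ending in a
1-channel grid of raw patch scores. Its receptive field is far smaller than
a training patch, so decisions are local.

Weights are initialised normal(0, 0.02) under a seed; instance norm keeps
no running statistics, so batch size 1 is exact. Both networks run on
`freqcycle.nn`, a small numpy reverse-mode autodiff engine written for this
package (im2col convolutions, an FFT-magnitude op with analytic adjoint,
Adam); float64 throughout, bit-deterministic on CPU under a fixed seed.

## Training

Per iteration: one joint update of both generators on the full objective,
then one update of each discriminator at half weight on (real, pooled-fake)
pairs. Fakes are drawn through a history pool of size 50 (probability 1/2
of replaying an older fake; size 0 disables). Each network has its own Adam
optimizer with betas (0.5, 0.999); lr 0.0004 for generators, 0.0002 for
discriminators, flat for the first half of the 30,000 iterations and
decayed linearly to zero over the second half. (The discrete sum of the
schedule is 22,500.5 x base_lr; the idealised closed form 22,500 x base_lr
holds to a half step of the ramp.)

Patch sampling per step: a CBCT and a CT scan are chosen independently and
uniformly (any patient with any patient), both are body-masked, the CT
field-of-view is truncated to the CBCT's, volumes smaller than the patch
are air-padded, and a patch position is rejection-sampled until its centre
lies inside the body (64 tries, then any position) — all-air patches carry
no signal. Patches are normalised to [-1, 1] through the training window.

Checkpoints serialise all four networks, all optimizer moments, the image
pools' contents and every RNG state; training resumes bit-identically from
an interruption (this required checkpointing the pools — without them the
discriminators see different fakes after a resume).

Whole-volume inference tiles the normalised volume with sliding windows
(default 50 % overlap), blends tiles with uniform weights normalised to a
partition of unity, and maps the result back to HU with the inverse window.

## Synthetic data

The generator stands in for a private clinical cohort and defines the
conditions of every test:

- **Phantom CT**: ellipsoidal body (~40 HU) with two lungs (-750), a heart
  (50), rib-like shell arcs and a spine cylinder (700) and an optional
  tumor sphere (30) inside the right lung, plus N(0, 10 HU) texture inside
  the body; air is exactly -1000. Default grid 32 x 96 x 96 voxels at
  1.2695 x 1.2695 x 3 mm (the cohort-modal spacing the pipeline targets).
  HU targets are standard tissue values and configurable; organ semi-axes
  jitter across synthetic patients.
- **CBCT degradation**, applied in order: affine HU miscalibration (scale
  then shift; defaults 1.0 and +40 HU), 24 alternating-sign angular streak
  rays of 60 HU shared across slices (sparse-view-like, not a physical
  scatter simulation), 1 mm Gaussian blur, 20 HU additive noise, and an
  optional smooth low-frequency deformation (off by default so phantom
  pairs stay voxel-aligned). The all-zero specification is the identity,
  and each knob alone weakly worsens MAE/MSE in expectation — both are
  tested.

What passing tests on this data do *not* show: real CBCT scatter physics,
reconstruction artifacts, anatomical variability beyond ellipsoid jitter,
or the clinical-scale training regime (see problem sizes below).

## Cohort procedures

Common spacing: the most frequent spacing in the cohort, ties broken toward
the smaller spacing — the reading of the (ambiguous) three-step ranking
procedure that minimises interpolation for the majority of scans. Weak
pairs: per patient, the CT/CBCT pair with the smallest calendar-day gap,
at most one day (larger gaps risk genuine anatomical change); ties break to
the earlier CT, then the earlier CBCT. Deformable registration of the
paired CT onto the CBCT is delegated to external tooling; the package emits
the machine-readable pair manifest that drives it.

## Numerical conventions and edge cases

- PSNR uses the per-image reference maximum (not a fixed range) and returns
  +inf at zero MSE; NMSE on an all-zero reference is an error — "perfect"
  and "undefined" are kept distinct.
- SSIM: `windowed` (default) averages the single-window formula over
  uniform 7^3 neighbourhoods; `global` evaluates it once on whole-volume
  moments. c1 = (0.01 R)^2, c2 = (0.03 R)^2 with R defaulting to 3000 (the
  evaluation clip width). Dice of two empty masks is 1 by convention.
- The vanilla adversarial loss validates scores lie in (0, 1); least
  squares accepts raw scores.
- Mask resampling is nearest-neighbour; intensity resampling under linear
  interpolation never leaves the input min/max.

## Problem sizes

Tests and the acceptance script run scaled-down configurations chosen to
exercise every code path on one CPU: phantoms of 12-32 slices, patches of
(8, 32, 32) or (4, 16, 16), generator widths of 2-4 base filters, and
50-step training runs. These are the package's own smoke-scale conditions;
the default configuration (16 x 320 x 320 patches, 30,000 iterations,
width 16) is the published recipe and is what `freqcycle train` runs when
given no overrides. A 50-step run shows the expected qualitative behaviour
(cycle losses fall; the frequency-loss generator preserves spectral content
better than the baseline), not converged translation quality.

## Known limitations

- No GPU path; the numpy engine is practical for smoke-scale experiments
  and correctness work, not for the full 30,000-iteration clinical recipe.
- The MIND descriptor loss and combined MIND+frequency configurations are
  not implemented (the structure-loss interface accepts new entries).
- DICOM series reading, CT reconstruction and scatter physics are out of
  scope; I/O is NIfTI/NRRD/MetaImage.
- Dice-based evaluation consumes user-supplied masks; no auto-segmentation
  model is bundled.
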