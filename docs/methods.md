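# Methods

## Problem and model

Laser interstitial thermal therapy (LITT) for mesial temporal lobe epilepsy
produces ablation lesions whose segmentation models are starved for training
data: cohorts number in the tens of scans.  `lesionsynth` implements a
two-stage generative model that expands such datasets by synthesising new
lesions — first a new binary lesion *mask*, then a new lesion *image* guided
by that mask — so that every synthetic image comes with a pixel-perfect
label, unlike whole-image GAN approaches.

Each stage is an adversarial 3D variational auto-encoder operating on
fixed-size cubes (64³ in the reference protocol; the test suite uses 16³):

* **Encoder** `E`: a stack of stride-2 3×3×3 convolutions, each followed by
  instance normalisation and LeakyReLU, ending in two linear heads that
  parameterise a diagonal Gaussian posterior `q(z|x) = N(mu, diag(exp(logvar)))`.
  Latent draws use the reparameterisation `z = mu + exp(logvar/2) ⊙ eps`.
* **Mask decoder** `D_S(z, c)`: a mirror-image upsampling stack whose
  normalisation layers are modulated by a *condition embedding block* (CEB):
  linear layers map the lesion-size condition `c` to per-channel scale and
  bias, applied as `norm(h)·(1+gamma(c)) + beta(c)`.
* **Lesion decoder** `D_I(z, m)`: the same backbone with the CEB replaced by
  a *mask embedding block* (MEB): the mask is nearest-neighbour-resized to
  each feature resolution, passed through a shared 3×3×3 convolution and two
  parallel heads that emit voxel-wise scale and bias fields — spatially
  adaptive (SPADE-style) modulation.
* **Critic** `D`: a plain stride-2 convolutional stack with LeakyReLU, *no*
  normalisation, global average pooling and a linear score head.

Both decoders end in a sigmoid so outputs live in (0, 1).

The training objective per stage combines four terms:

    L_G     = w_adv · (−E[D(x_g)]) + w_rec · ‖x_g − x_r‖² + w_kl · KL(q(z|x_r) ‖ N(0, I))
    L_D     = E[D(x_g)] − E[D(x_r)] + λ · E[(‖∇_x̂ D(x̂)‖₂ − 1)²]

with `x̂` a per-sample uniform interpolation between real and generated
inputs and λ = 10.  Reconstruction and KL are evaluated in closed form,
summed within a sample and averaged over the batch (a `reduction="sum"` flag
restores the raw batch sum).

At inference (the "progressive" cascade): sample `z_shape ~ N(0, I)` and a
size condition → `D_S` → threshold at 0.5 (keeping the largest 26-connected
component; this clean-up can be disabled) → sample `z_int ~ N(0, I)` →
`D_I(z_int, mask)` → optionally paste the result into a host scan.

## Numerical core

No GPU framework is used: the package carries a compact reverse-mode
automatic-differentiation engine (`lesionsynth.autodiff`) over numpy arrays.
Convolution is decomposed into an `im2col` gather (adjoint: `col2im`
scatter-add) and a single-GEMM channel contraction; the vjp closures of
these primitives are themselves engine operations, so gradients remain
differentiable and the gradient penalty — a loss built from the norm of an
input gradient — can be optimised with respect to the critic's weights
(double backprop).  Volumes flow through convolutions in a channels-first,
batch-second (C, N, D, H, W) layout: every forward and backward product is
then one large GEMM with no transposed copies, which is what makes CPU
training affordable.  Activations and parameters are float32; the engine
weakens 0-d scalar constants to the array operand's dtype so float64 test
oracles retain full precision.

Every gradient path is tested against finite differences, the convolution
adjoint identities `⟨conv(x,w), g⟩ = ⟨x, ∇_x⟩ = ⟨w, ∇_w⟩`, and a
finite-difference check of the second-order penalty gradient.

## Parameters that matter

| Parameter | Default | Meaning |
| --- | --- | --- |
| `side` | 64 | cube edge length, voxels; must divide by 2^`n_levels` |
| `n_levels` | 4 | stride-2 encoder/decoder levels (bottleneck 4³ at side 64) |
| `base_channels` | 16 | channels after the first level, doubling per level |
| `latent_dim` | 128 | length of shape/intensity latent vectors |
| `leaky_slope` | 0.2 | LeakyReLU negative slope |
| `learning_rate` | 5e-5 | Adam, both optimisers; betas (0.5, 0.9) |
| `batch_size` | 13 | reference protocol value |
| `epochs` | 1000 | reference protocol value |
| `critic_steps` | 5 | critic updates per generator update |
| `w_rec, w_kl, w_adv` | 1, 0.1, 0.01 | loss weights (see below) |
| `gp_lambda` | 10 | gradient-penalty weight |

Depth, width and latent size are not pinned down by the reference protocol
and are exposed in `NetworkConfig`.

**Loss weights.**  The relative weighting of reconstruction, KL and
adversarial terms is an open choice.  With the reconstruction summed over
voxels, a vanishing KL weight leaves the posterior essentially
unregularised; latents drawn from the prior at inference are then
out-of-distribution for the decoder and the guidance signals (condition,
mask) are ignored.  The default `w_kl = 0.1` keeps prior samples usable
while preserving reconstruction quality; `w_adv = 0.01` keeps the
Wasserstein term from destabilising early training.  Both are configurable.

**Condition encoding.**  "Lesion size" is encoded as the normalised
log-volume `c = log(V)/log(side³) ∈ [0, 1]` — continuous and scale-robust
(0 for a single voxel, 1 for a full cube).

## Cube extraction and paste-back

`extract_cube` centres a `side`³ window on the mask's foreground centroid
(rounded), shifts it by the minimal amount needed to contain the mask
bounding box, zero-pads overhangs, and min–max normalises intensities to
[0, 1] with the window stored for exact inversion (per-cube rather than
per-volume normalisation; configurable at the call site by pre-scaling).
A constant cube maps to all zeros.  `paste_cube` de-normalises a synthetic
cube through the stored window and replaces voxels inside the new mask;
`blend_sigma > 0` feathers the transition just outside the mask with a
Gaussian-smoothed alpha (hard inside the mask, exactly untouched beyond a
3σ dilation); `blend_sigma = 0` is exact replacement.  Indices are 0-based,
origins are inclusive lower corners, ranges half-open.

## The phantom generator

Real post-LITT data are private, so the package ships a phantom module
whose samples have the statistical structure the model assumes:

* masks are unions of 1–3 overlapping random ellipsoids (each new lobe
  centred on a foreground voxel of the union, so masks are single
  26-connected components), rejection-sampled until the voxel count lies in
  `volume_range` — the range is respected *exactly*;
* the background is a Gaussian-smoothed uniform random field rescaled to
  [0.3, 0.7], mimicking smooth low-frequency brain intensity;
* inside the mask, intensity is offset by `texture_contrast·(1 + 0.5·speckle)`
  with smoothed Gaussian speckle (multiplicative texture), clipped to [0, 1].

Defaults: `side 64`, `volume_range (500, 8000)` voxels (≈0.2–3 % of the
cube, matching ablation-scale lesions), `texture_contrast 0.35`,
`background_smoothness 4` voxels.  The contrast default is chosen so that
lesions are separable from the background's own dynamic range — the regime
the generative model is intended for.

What the phantoms do *not* emulate: MR physics (bias fields, noise
correlation, partial volume), anatomy, multi-class lesions, or
inter-scanner variation.  Tests passing on phantoms demonstrate that the
machinery — conditioning, guidance, optimisation, sampling — works as
designed; they say nothing about realism on clinical data.

## Toy-scale protocol

CPU tests and the acceptance script run a scaled-down protocol chosen as
the smallest configuration at which the model's mechanisms are measurable:
side 16, `n_levels 2`, `base_channels 4`, `latent_dim 32`,
`embed_hidden 4`, `critic_steps 1`, batch 8, 50 epochs per stage on 200
phantoms with `volume_range (30, 400)`, `texture_contrast 0.35` and
`background_smoothness 2`, with loss weights `w_rec 1, w_kl 1, w_adv 0.01`
(the ELBO-consistent KL weight; at toy scale the size-conditioning pathway
only becomes measurable once the posterior is genuinely regularised).
Roughly 1250 optimisation steps are taken per stage, so the toy learning
rate is raised to 2e-3 (the reference 5e-5 is tuned for 1000-epoch runs);
Adam's adaptive scaling makes this the step-budget-appropriate choice.

## Numerical choices

* Instance normalisation uses ε = 1e-5 inside the square root.
* Modulation is `norm·(1+gamma)+beta` with zero-initialised gamma/beta
  heads, so untrained CEB/MEB blocks are exactly the identity on
  normalised features.
* Nearest-neighbour mask resizing samples source index
  `floor((i + 0.5)·factor)` (centre alignment).
* Upsampling is nearest-neighbour repeat + convolution (no transposed
  convolutions, avoiding checkerboard artifacts).
* Weight init is Kaiming-normal with the LeakyReLU gain; gamma/beta heads
  start at zero.
* The critic has no normalisation layers anywhere — batch-coupled
  statistics would invalidate the per-sample gradient penalty.
* Mask binarisation threshold 0.5; empty post-threshold masks are
  resampled with fresh sub-seeds up to 5 times, then flagged rather than
  raised.
* Degenerate normalisation (max = min) maps to an all-zero cube.
* SSIM uses a Gaussian window (σ 1.5), size 7 for volumes ≤ 32³ and 11
  otherwise, constants C1 = (0.01·range)², C2 = (0.03·range)²; a border of
  half a window is excluded from the average.  NMSE is normalised by the
  reference image's energy and reported in percent.  Surface distances
  (ASD, 95 % Hausdorff) are voxel-unit by default, spacing-aware when a
  voxel spacing is passed.
* PSNR of identical volumes is reported as `inf`.

## Determinism

Every stochastic step — phantom sampling, weight init, shuffling, posterior
draws, interpolation draws, inference latents — derives from an explicit
seed through `numpy.random.Generator`.  Checkpoints store the optimiser
moments and the generator's bit-state, so train-k-then-resume reproduces an
uninterrupted run bit for bit on the same machine.  Single-threaded runs
are bitwise reproducible; BLAS thread count does not change results beyond
floating-point summation order in GEMMs.

## Known limitations

* The networks are CPU-bound numpy; the reference 64³/1000-epoch protocol
  is out of reach at desk scale — the package targets method correctness
  and small-cohort experimentation, not production training speed.
* Only a scalar size condition is implemented; location or shape
  conditions would need a wider `condition_dim` and their own encoders.
* The largest-component clean-up at inference is an extension beyond the
  core model (raw sigmoid masks can contain speckle); it can be disabled.
* Quality numbers reported on phantoms are not comparable to values
  measured on clinical MRI.
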