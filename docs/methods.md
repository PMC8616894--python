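# Methods

## Problem and model

`mrcontrast` synthesizes 2-D MR images at a requested tissue contrast.  In
MR imaging, contrast is governed by the sequence parameters echo time (TE),
repetition time (TR) and the use of a fat-saturation (FS) pulse; protocols
vary widely across sites and scanners, so a model that can retarget an
existing image to a different parameterization has practical value
(replacing missing contrasts, protocol previews, augmentation).

The core model is a conditional image-to-image GAN:

* **Generator** — a U-Net of residual blocks (3x3 convolutions, leaky ReLU
  slope 0.2, nearest-neighbour upsampling + convolution, strided-convolution
  downsampling).  The acquisition parameters enter through adaptive
  instance normalization,

      AdaIN(x, y) = alpha(y) * (x - mu(x)) / sigma(x) + beta(y),

  where mu, sigma are per-sample per-channel spatial moments
  (epsilon = 1e-5 inside sigma) and alpha, beta are single affine layers of
  the scaled label vector y = (TE/50 ms, TR/5000 ms, FS).  Source-image
  labels are injected into every encoder residual block, target labels into
  the bottleneck and every decoder block.  Each injection site owns its
  projections; they are identity-initialized (alpha = 1, beta = 0), so an
  untrained generator is exactly label-invariant and early training behaves
  like an unconditioned U-Net.
* **Discriminator** — six residual blocks without normalization (compatible
  with the R1 penalty) onto a single raw score.
* **Auxiliary classifier (AC)** — a separately pretrained network
  predicting (TE, TR) by regression and FS by classification from an image;
  used to score conditioning fidelity and, in the unpaired training regime,
  to guide the generator.  The desk-scale backbone is a small CNN (four
  strided conv blocks; mean and second-moment global pooling feed a small
  hidden layer and three heads).  Second-moment pooling matters: plain
  average pooling washes out small bright structures, which carry the FS
  evidence.  A large pretrained backbone (EfficientNet-B3) would need a
  deep-learning framework that is not available here, so that backbone name
  is rejected with a clear error.

### Losses

* Reconstruction: `omega * (1 - MS-SSIM) + (1 - omega) * L1` with
  omega = 0.84.  MS-SSIM follows the standard 5-scale construction (11x11
  Gaussian window, sigma 1.5, k1/k2 = 0.01/0.03, per-scale exponents
  0.0448/0.2856/0.3001/0.2363/0.1333); on images too small for five dyadic
  scales the scale count is reduced and the exponents renormalized to sum
  to one (64x64 supports 3 scales, 32x32 supports 2).  Contrast-structure
  terms are clamped at 1e-6 before exponentiation so near-zero local
  statistics cannot produce NaNs.
* Adversarial: non-saturating loss in softplus form,
  `d_loss = E[softplus(-D(real))] + E[softplus(D(fake))]`,
  `g_loss = E[softplus(-D(fake))]`, with the R1 penalty
  `(gamma/2) E[||grad_x D(x)||^2]` on real samples every iteration
  (gamma = 1, no lazy regularization).
* Cycle consistency (unpaired regime): L1 of the round trip in both
  directions; a single conditioned generator serves as both directions by
  swapping source/target labels.
* Conditioning (unpaired regime): MSE over scaled TE and TR (averaged)
  plus binary cross-entropy over FS, weighted lambda_c = 10 in the
  generator objective.  It is applied on the unpaired branch only by
  default (configurable), since that branch is the one trained on random
  target labels.

**Loss balance.**  The training objective's relative weighting of the
reconstruction and adversarial terms is a free design choice here; the
package follows the pix2pix convention and weights the reconstruction term
100x (config field `recon_weight`), with the cycle term weighted 10x.
Early experiments with equal weighting let adversarial noise swamp the
supervised signal at desk scale (SSIM degraded while NMSE improved).

### Optimization

Adam with lr 1e-4, beta1 = 0, beta2 = 0.99 for generator and
discriminator; batch 8; one discriminator step per generator step; an
exponential moving average of generator parameters (decay 0.999) is used at
inference.  The AC is a plain supervised regressor, so it uses
conventional Adam momentum (beta1 = 0.9, lr 1e-3, batch 64); the beta1 = 0
choice is a GAN-stability measure and is not carried over.

### Training-data regimes (model variants 1-6)

The six variants form a cumulative ladder, each adding one switch:
(1) pix2pix baseline on non-FS -> FS pairs with L1 + adversarial + R1,
labels unused; (2) target labels into the decoder via AdaIN; (3) source
labels into the encoder; (4) the weighted L1/MS-SSIM reconstruction loss;
(5) pairs with non-FS targets added; (6) unpaired non-FS images added,
trained under cycle consistency and the AC conditioning loss with random
target labels drawn from the dataset's label sampler, at a rate equal to
the unpaired share of the data.  Variant 6 requires a pretrained AC and
fails fast without one.  All variants build identical parameter sets
(label projections are constructed even when unused), so ablations compare
wiring, not capacity.

## Synthetic data: the spin-echo phantom

Real training data for this task are knee DICOM series whose contrast is an
implicit function of TE/TR/FS.  The simulator makes that function explicit.
A `TissueMap` assigns each pixel a class (background, fat, muscle, fluid,
bone, cartilage) with proton density, T1 and T2 drawn from standard 1.5 T
literature ranges, plus a smooth +/-5 % within-structure variation.
Geometry is knee-like in one deliberate way: the first structure is always
a large fat region (subcutaneous/marrow fat is the dominant bright tissue
that a fat-saturation pulse visibly removes) and fluid appears only as
small pockets.  Without this, FS detection is genuinely ambiguous (a bright
fluid blob is indistinguishable from unsuppressed fat), which no classifier
can overcome; with it, FS detection is reliably learnable, matching the
near-perfect FS discrimination reported on real data.

Rendering uses the classical spin-echo equation
`S = PD (1 - exp(-TR/T1)) exp(-TE/T2)`; FS multiplies fat-class pixels by
0.05; Gaussian noise (default sd 0.01, configurable; Rician noise is out of
scope) is added; the image is clipped and mapped to [-1, 1] using the
map's peak proton density as the fixed scale.  The fixed scale (rather
than the per-render maximum) is what makes per-pixel intensity monotone,
non-increasing in TE and non-decreasing in TR — the property the
conditioning tests rely on — and preserves the absolute-intensity cues the
AC needs.

The label sampler emulates clinical clustering: a non-FS cluster
(TE 25-35 ms, TR 2000-3500 ms), an FS cluster (TE 30-45 ms,
TR 2500-4500 ms), and 10 % uniform mass over the admissible box
(TE <= 50 ms, TR <= 5000 ms).  Paired samples render one map under a
non-FS source label and a target label (FS with probability 0.8); the
number of paired slots is chosen so the *sample* share of pairs equals the
requested `pair_fraction` (clinical reference ~0.43).

What the phantom does **not** emulate: k-space acquisition, coil
sensitivities, chemical shift, partial volume, flip-angle dependence,
through-plane motion, scanner intensity variation.  A green test on
phantoms therefore establishes that the method's mechanics work
(conditioning, losses, training dynamics, metrics), not clinical image
quality.

## Curation rules

Filters keep TE <= 50 ms and TR <= 5000 ms (inclusive bounds: "over the
limit" is excluded), 1.5 T, Siemens (both wildcardable).  Central-slice
selection keeps the k = 14 slices centered on floor(n/2) (window
[floor(n/2) - k//2, floor(n/2) + (k+1)//2)).  Pairing groups records by
patient ID, study UID, image orientation (element tolerance 1e-3), slice
location (tolerance 0.5 mm; DICOM floats rarely match bitwise) and slice
thickness, then emits one ordered (non-FS source, target) pair per
combination with distinct series UIDs.  Preprocessing maps intensities
affinely to [-1, 1] (constant images to -1) and resizes bilinearly under
the half-pixel-center convention.  Augmentation is random shift (up to 10 %
of the side) and zoom (0.9-1.1), reflection-padded, shared between source
and paired target.  Real-DICOM reading needs pydicom and flags FS by a
header heuristic (logged per file), since no single DICOM tag encodes it.

## Evaluation metrics

NMSE `||x - x'||^2 / ||x||^2` (asymmetric, ground truth in the
denominator); PSNR with MAX taken as the *joint* value range of the two
images; SSIM with c1 = (0.01 L)^2, c2 = (0.03 L)^2.  SSIM defaults to the
conventional Gaussian-windowed mean (the single-scale case of the MS-SSIM
loss, shared windowing verified in tests); a `windowed=False` mode computes
the literal global-statistics formula.  Metrics are computed on [-1, 1]
images and every report records the convention in its header.  Identical
images give infinite PSNR; such pairs are excluded from aggregates with a
warning.  A two-sample t-test utility supports model comparisons.

## Numerical substrate

No deep-learning framework is available in the target environment, so the
package includes a minimal reverse-mode autodiff engine on numpy
(`mrcontrast.autodiff`): convolution via im2col/col2im with loop-free
overlap-add, and every primitive's backward rule written in terms of the
same primitives, so gradients are themselves differentiable — the R1
penalty backpropagates through a gradient (double backprop) without
special-casing.  Networks run in float32; metric-grade computations run in
float64.  Residual additions are scaled by 1/sqrt(2) to keep activation
variance flat with depth; the generator adds a global input-to-output
residual before the tanh, so training starts near the identity map.

## Desk scale and run sizing

The reference setup trains 200 K iterations at 256x256 on a GPU.  On this
package's CPU engine a desk-scale analogue must be much smaller; run sizes
below were fixed from wall-clock budgets before outcomes were measured:

* AC parameter recovery: 2,000 noise-free 64x64 phantoms, 2,000 iterations,
  batch 64 (~4 min).
* GAN smoke run: 500 training pairs at 32x32, 500 iterations, batch 8,
  generator filters 8-16-32, lr 1e-3, EMA decay 0.99 (~4 min).  The larger
  lr and smaller EMA horizon scale with the ~400x-shorter run: lr keeps the
  total update budget comparable and the EMA horizon stays a fixed fraction
  of the run.  The full-scale configuration (256x256, filters 64-512,
  lr 1e-4, decay 0.999, 200 K iterations) remains reachable through config.

## Known limitations

* 2-D only; single-image input; no registration.
* The AC's TE/TR regression on random phantoms hits an identifiability
  ceiling rather than a data ceiling: each structure's proton density is
  itself random (+-10-25 % per class), so the intensity of any single
  region constrains TR only to roughly 250-500 ms.  Held-out TE/TR MAE
  plateaus around 3.3 ms / 440 ms (0.065 / 0.088 scaled) with no train/val
  gap, and widening the network or rescheduling the optimizer does not
  move it.  FS classification saturates first (99.5-100 %), as it does on
  real data.
* The cycle/conditioning regime (variant 6) is implemented and wired but
  its desk-scale runs are short; no claim is made that it improves over
  variant 5 (it did not in the reference setting either).
* The autodiff engine is written for clarity and small models; it is not a
  general framework (no GPU, no graph optimization, basic-indexing
  adjoints assume non-repeating indices).
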