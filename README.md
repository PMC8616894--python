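# mrcontrast

Retrospective MR contrast synthesis: an acquisition-parameter-conditioned
image-to-image GAN, together with a spin-echo phantom simulator that makes
the whole method trainable and verifiable on one CPU.

## Who this is for

MR image contrast is set at scan time by the sequence parameters — echo
time (TE), repetition time (TR) and fat saturation (FS) — and those
parameterizations vary widely across sites and scanners.  `mrcontrast` is
for researchers who want to translate an existing 2-D MR image to a
*different* parameterization: synthesize a fat-saturated image from a
non-fat-saturated one, or interpolate contrast continuously over the
TE/TR plane.  Because real knee DICOM data cannot ship with a package, a
physics phantom stands in for it: every experiment below runs end to end
from nothing.

## The model

A residual U-Net generator translates an image given two label vectors,
`y = (TE/50 ms, TR/5000 ms, FS)` for the source and the target contrast.
Labels are injected through adaptive instance normalization

    AdaIN(x, y) = alpha(y) * (x - mu(x)) / sigma(x) + beta(y)

with per-site learned affine projections alpha, beta (source labels in the
encoder, target labels in the decoder).  Training combines

* a weighted reconstruction loss `0.84 * (1 - MS-SSIM) + 0.16 * L1`,
* a non-saturating adversarial loss with R1 gradient penalty (gamma = 1),
* and, for the unpaired training regime, cycle consistency plus a
  conditioning loss (weight 10) from a separately pretrained auxiliary
  classifier that recovers (TE, TR, FS) from images.

Six training variants form the standard ablation ladder from a pix2pix
baseline (no labels) up to unpaired training with cycle/conditioning
losses.  Evaluation uses NMSE, PSNR and SSIM plus the auxiliary
classifier's TE/TR mean absolute error and FS accuracy.

The phantom renders random knee-like tissue maps (fat, muscle, fluid,
bone, cartilage with literature T1/T2/PD values) through the spin-echo
equation `S = PD (1 - e^(-TR/T1)) e^(-TE/T2)`, so the correct effect of
any TE/TR/FS request is known analytically — the simulator is both the
training world and the test oracle.

No deep-learning framework is required: the package carries a small numpy
autodiff engine (with double backprop for R1) in `mrcontrast.autodiff`.

## Worked example

```python
import numpy as np
from mrcontrast.phantom import make_synthetic_dataset, SyntheticDataset
from mrcontrast.curation import pairs_from_synthetic
from mrcontrast.training import VariantConfig, train_gan, translator_from_bundle
from mrcontrast.metrics import evaluate_reconstruction

ds = make_synthetic_dataset(seed=21, n_subjects=360, slices_per_subject=1,
                            pair_fraction=1.0, height=32, width=32)
train = SyntheticDataset([s for s in ds.samples if s.subject_id < 300],
                         ds.seed, ds.label_sampler)
held  = SyntheticDataset([s for s in ds.samples if s.subject_id >= 300],
                         ds.seed, ds.label_sampler)

cfg = VariantConfig(variant=5, iterations=300, image_size=32, lr=1e-3,
                    ema_decay=0.99, gen_filters=(8, 16, 32),
                    disc_filters=(8, 16, 32, 32, 32, 32), seed=21)
bundle, history = train_gan(train, cfg)

pairs = pairs_from_synthetic(held)
model = evaluate_reconstruction(pairs, translator_from_bundle(bundle))
identity = evaluate_reconstruction(pairs, lambda img, ys, yt: img)
print("model    SSIM", round(model.aggregates()["ssim"]["mean"], 3))
print("identity SSIM", round(identity.aggregates()["ssim"]["mean"], 3))
```

Output from this exact script (one CPU, ~1 minute of training):

```
model    SSIM 0.349
identity SSIM 0.183
```

The trained translator reconstructs held-out target contrasts (here mostly
non-FS -> FS translations) with higher structural similarity than copying
the input — after 300 iterations the generator has learned to suppress the
fat signal when the target label asks for it.  `networks.contrast_grid`
produces TE x TR interpolation grids from the same checkpoint, and
`training.pretrain_ac` trains the auxiliary classifier that scores how
faithfully a synthetic image carries its requested acquisition parameters.

A command-line interface wraps the same functionality:

```
mrcontrast simulate --seed 1 --n-subjects 100 --slices 4 --size 64 --out data/
mrcontrast train --data data/ --variant 5 --out runs/v5/
mrcontrast evaluate --checkpoint runs/v5/checkpoint.npz --data data/ --out runs/v5/eval/
mrcontrast interpolate --checkpoint runs/v5/checkpoint.npz --image img.npy \
    --source-te 30 --source-tr 2800 --te-list 15,30,45 --tr-list 2000,4000 --fs 0 --out grid.png
```

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch — it simulates a paired phantom dataset, pretrains the auxiliary
classifier, trains the variant-5 GAN at desk scale, and evaluates
reconstruction and conditioning on held-out subjects — then writes its
JSON results file:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness derives from `--seed`.  The run takes a few minutes on one
CPU and prints the evaluation reports it computes along the way.

See `docs/methods.md` for the full model description, parameter choices,
what the phantom does and does not emulate, and known limitations.
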