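"""Optimization loops: auxiliary-classifier pretraining and GAN training
across the six cumulative experiment variants.

Variant ladder (each variant adds exactly one feature to its predecessor):

1. pix2pix baseline — non-FS -> FS pairs, L1 reconstruction +
   non-saturating adversarial loss with R1 (labels unused).
2. target labels injected into the decoder via AdaIN.
3. source labels additionally injected into the encoder.
4. reconstruction loss switches to the weighted L1/MS-SSIM form.
5. pairs with non-fat-saturated targets join the training data.
6. unpaired non-FS images join, trained under cycle consistency and the
   auxiliary-classifier conditioning loss (lambda_c = 10) with random
   target labels; requires a pretrained AC.

Optimizers follow the reference setup: Adam(lr 1e-4, beta1 = 0,
beta2 = 0.99), batch size 8 for the GAN and 64 for the AC, one
discriminator update per generator update, R1 on real samples every
iteration, and an exponential moving average (decay 0.999) of the
generator parameters used at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .conditioning import scale_labels
from .curation import augment
from .losses import (LossWeights, ModelBundle, conditioning_loss, l1_loss,
                     nonsat_gan_losses, r1_penalty, recon_loss)
from .networks import (Discriminator, DiscriminatorConfig, Generator,
                       GeneratorConfig, SmallCNNClassifier)
from .phantom import SyntheticDataset, _subseed

__all__ = [
    "VariantConfig",
    "variant_features",
    "Batch",
    "sample_batch",
    "pretrain_ac",
    "train_gan",
    "ema_update",
]

ema_update = nn.ema_update  # re-exported: shadow <- d*shadow + (1-d)*current


def variant_features(variant: int) -> dict[str, bool]:
    """The cumulative feature switches enabled by each model variant."""
    if not 1 <= variant <= 6:
        raise ValueError("variant must lie in 1..6")
    return {
        "inject_target_labels": variant >= 2,
        "inject_source_labels": variant >= 3,
        "ms_ssim_recon": variant >= 4,
        "include_nonfs_targets": variant >= 5,
        "use_unpaired": variant >= 6,
    }


@dataclass
class VariantConfig:
    """Configuration of one training run of models 1-6."""

    variant: int = 5
    weights: LossWeights = field(default_factory=LossWeights)
    lr: float = 1e-4
    ac_lr: float = 1e-3
    beta1: float = 0.0
    beta2: float = 0.99
    batch_size: int = 8
    ac_batch_size: int = 64
    iterations: int = 2000
    ac_iterations: int = 2000
    ema_decay: float = 0.999
    seed: int = 0
    image_size: int = 64
    gen_filters: tuple[int, ...] = (32, 64, 128, 256)
    disc_filters: tuple[int, ...] = (64, 128, 256, 512, 512, 512)
    res_blocks_per_level: int = 1
    augment_data: bool = True
    # relative weight of the reconstruction term in the generator objective;
    # unstated in the reference setup, fixed to the pix2pix convention
    recon_weight: float = 100.0
    # cycle-consistency weight for variant 6 (CycleGAN convention)
    cycle_weight: float = 10.0
    # model 6: apply the conditioning loss on the unpaired branch only
    conditioning_on_paired: bool = False

    @property
    def features(self) -> dict[str, bool]:
        return variant_features(self.variant)

    def generator_config(self) -> GeneratorConfig:
        f = self.features
        return GeneratorConfig(
            encoder_filters=tuple(self.gen_filters), base_size=self.image_size,
            inject_source_labels=f["inject_source_labels"],
            inject_target_labels=f["inject_target_labels"],
            res_blocks_per_level=self.res_blocks_per_level)

    def discriminator_config(self) -> DiscriminatorConfig:
        return DiscriminatorConfig(filters=tuple(self.disc_filters),
                                   base_size=self.image_size)

    def diff(self, other: "VariantConfig") -> dict[str, tuple]:
        """Feature switches on which two variant configs differ."""
        a, b = self.features, other.features
        return {k: (a[k], b[k]) for k in a if a[k] != b[k]}


@dataclass
class Batch:
    """One training batch; unpaired entries have no target image."""

    src_images: np.ndarray          # (B, H, W)
    src_labels: np.ndarray          # (B, 3) scaled
    tgt_images: np.ndarray | None   # (B_paired, H, W)
    tgt_labels: np.ndarray          # (B, 3) scaled
    is_unpaired: np.ndarray         # (B,) bool


def _label_vec(label) -> np.ndarray:
    return scale_labels(label.te_ms, label.tr_ms, label.fs)


def _eligible_pairs(dataset: SyntheticDataset, variant: int):
    pairs = dataset.pairs()
    if variant < 5:
        pairs = [(s, t) for s, t in pairs if t.label.fs == 1]
    return pairs


def sample_batch(dataset: SyntheticDataset, config: VariantConfig,
                 rng: np.random.Generator) -> Batch:
    """Draw one batch according to the variant's data regime.

    Variants 1-4 draw non-FS -> FS pairs only; variant 5 includes pairs with
    non-FS targets; variant 6 additionally draws unpaired non-FS images with
    probability equal to their share of the eligible data, assigning each a
    random target label from the dataset's label sampler.
    """
    pairs = _eligible_pairs(dataset, config.variant)
    unpaired = dataset.unpaired(fs=0) if config.features["use_unpaired"] else []
    if not pairs and not unpaired:
        raise ValueError("dataset contains no eligible samples for this variant")
    n_total = 2 * len(pairs) + len(unpaired)
    p_unpaired = len(unpaired) / n_total if n_total else 0.0

    src_imgs, src_labels, tgt_imgs, tgt_labels, unpaired_mask = [], [], [], [], []
    for _ in range(config.batch_size):
        if unpaired and rng.random() < p_unpaired:
            s = unpaired[rng.integers(0, len(unpaired))]
            tgt_label = dataset.label_sampler.sample(rng)
            src_imgs.append(s.image)
            src_labels.append(_label_vec(s.label))
            tgt_labels.append(_label_vec(tgt_label))
            unpaired_mask.append(True)
        else:
            s, t = pairs[rng.integers(0, len(pairs))]
            src_imgs.append(s.image)
            src_labels.append(_label_vec(s.label))
            tgt_imgs.append(t.image)
            tgt_labels.append(_label_vec(t.label))
            unpaired_mask.append(False)
    return Batch(
        src_images=np.stack(src_imgs).astype(np.float32),
        src_labels=np.stack(src_labels).astype(np.float32),
        tgt_images=np.stack(tgt_imgs).astype(np.float32) if tgt_imgs else None,
        tgt_labels=np.stack(tgt_labels).astype(np.float32),
        is_unpaired=np.array(unpaired_mask, dtype=bool))


def _augment_batch(images: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(images)
    for i in range(len(images)):
        out[i] = augment(images[i], seed=int(rng.integers(0, 2 ** 31 - 1)))
    return out


# --------------------------------------------------------------------------
# auxiliary-classifier pretraining
# --------------------------------------------------------------------------

def pretrain_ac(dataset: SyntheticDataset, config: VariantConfig,
                ac: SmallCNNClassifier | None = None,
                val_fraction: float = 0.1,
                progress: bool = False) -> tuple[SmallCNNClassifier, dict]:
    """Train the auxiliary classifier to recover (TE, TR, FS) from images.

    MSE on the scaled TE/TR regressions plus BCE on the FS flag, the shared
    shift/zoom augmentation, and a held-out validation split by subject.
    Returns the classifier and a report with TE/TR MAE (ms) and FS accuracy.
    """
    samples = list(dataset.samples)
    if not samples:
        raise ValueError("dataset is empty")
    rng = np.random.default_rng(_subseed(config.seed, "ac"))
    subjects = sorted({s.subject_id for s in samples})
    n_val = max(1, int(round(val_fraction * len(subjects))))
    val_subjects = set(subjects[-n_val:])
    train = [s for s in samples if s.subject_id not in val_subjects]
    val = [s for s in samples if s.subject_id in val_subjects]

    ac = ac or SmallCNNClassifier(rng=np.random.default_rng(_subseed(config.seed, "ac-init")))
    # the reference beta1=0 choice is specific to the GAN; the AC, a plain
    # supervised regressor, uses conventional Adam momentum
    opt = nn.Adam(ac.parameters(), lr=config.ac_lr, beta1=0.9,
                  beta2=config.beta2)
    images = np.stack([s.image for s in train]).astype(np.float32)
    labels = np.stack([_label_vec(s.label) for s in train]).astype(np.float32)

    history = []
    base_lr = opt.lr
    for it in range(config.ac_iterations):
        # cosine decay to 10% of the base rate over the run
        opt.lr = base_lr * (0.1 + 0.45 * (1 + np.cos(np.pi * it / config.ac_iterations)))
        idx = rng.integers(0, len(train), size=config.ac_batch_size)
        batch = images[idx]
        if config.augment_data:
            batch = _augment_batch(batch, rng)
        pred = ac(Tensor(batch))
        loss = conditioning_loss(pred, labels[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss.data))
        if progress and (it + 1) % 200 == 0:
            print(f"[ac] iter {it + 1}/{config.ac_iterations} loss {loss.data:.4f}")
    ac.trained = True

    report = evaluate_ac(ac, val)
    report["train_loss_final"] = float(np.mean(history[-50:])) if history else float("nan")
    return ac, report


def evaluate_ac(ac: SmallCNNClassifier, samples) -> dict:
    """Held-out TE/TR MAE in ms and FS accuracy of an auxiliary classifier."""
    from .conditioning import TE_MAX_MS, TR_MAX_MS

    if not samples:
        raise ValueError("no validation samples")
    images = np.stack([s.image for s in samples]).astype(np.float32)
    labels = np.stack([_label_vec(s.label) for s in samples])
    with ad.no_grad():
        preds = ac(Tensor(images)).data
    te_err = np.abs(preds[:, 0] - labels[:, 0])
    tr_err = np.abs(preds[:, 1] - labels[:, 1])
    fs_ok = (preds[:, 2] > 0) == (labels[:, 2] > 0.5)
    return {
        "te_mae_scaled": float(te_err.mean()),
        "tr_mae_scaled": float(tr_err.mean()),
        "te_mae_ms": float(te_err.mean() * TE_MAX_MS),
        "tr_mae_ms": float(tr_err.mean() * TR_MAX_MS),
        "fs_accuracy_pct": float(100.0 * fs_ok.mean()),
        "n_val": int(len(samples)),
    }


# --------------------------------------------------------------------------
# GAN training
# --------------------------------------------------------------------------

def train_gan(dataset: SyntheticDataset, variant: VariantConfig,
              ac: SmallCNNClassifier | None = None,
              progress: bool = False) -> tuple[ModelBundle, pd.DataFrame]:
    """Alternating discriminator/generator optimization for one variant.

    Returns the trained bundle (generator with EMA shadow attached as
    ``bundle.G.ema_shadow``) and the per-iteration loss history.
    """
    feats = variant.features
    if feats["use_unpaired"] and ac is None:
        raise RuntimeError("variant 6 requires a pretrained auxiliary classifier")
    if ac is not None and not getattr(ac, "trained", False):
        raise RuntimeError("auxiliary classifier must be pretrained")

    rng = np.random.default_rng(_subseed(variant.seed, "gan"))
    G = Generator(variant.generator_config(),
                  rng=np.random.default_rng(_subseed(variant.seed, "gen-init")))
    D = Discriminator(variant.discriminator_config(),
                      rng=np.random.default_rng(_subseed(variant.seed, "disc-init")))
    opt_g = nn.Adam(G.parameters(), lr=variant.lr, beta1=variant.beta1,
                    beta2=variant.beta2)
    opt_d = nn.Adam(D.parameters(), lr=variant.lr, beta1=variant.beta1,
                    beta2=variant.beta2)
    ema = nn.EMA(G, decay=variant.ema_decay)
    weights = variant.weights
    n_scales = _n_scales_for(variant.image_size)

    history = []
    for it in range(variant.iterations):
        batch = sample_batch(dataset, variant, rng)
        if variant.augment_data:
            batch = _augment_paired(batch, rng)
        row = {"iteration": it}

        src = batch.src_images[:, None]
        ys, yt = Tensor(batch.src_labels), Tensor(batch.tgt_labels)

        # --- discriminator step (R1 on real samples) ---
        with ad.no_grad():
            fake = G(Tensor(src), ys, yt).data
        paired = ~batch.is_unpaired
        real_parts = []
        if batch.tgt_images is not None:
            real_parts.append(batch.tgt_images[:, None])
        if batch.is_unpaired.any():
            real_parts.append(src[batch.is_unpaired])
        real = np.concatenate(real_parts, axis=0)
        d_fake = D(Tensor(fake))
        d_real = D(Tensor(real))
        _, d_loss = nonsat_gan_losses(d_real, d_fake)
        r1 = r1_penalty(D, real, weights)
        opt_d.zero_grad()
        (d_loss + r1).backward()
        opt_d.step()
        row["d_loss"] = float(d_loss.data)
        row["r1"] = float(r1.data)

        # --- generator step ---
        fake_t = G(Tensor(src), ys, yt)
        g_adv, _ = nonsat_gan_losses(Tensor(np.zeros(1, dtype=np.float32)),
                                     D(fake_t))
        g_loss = g_adv
        row["g_adv"] = float(g_adv.data)
        if batch.tgt_images is not None:
            pred_paired = fake_t[np.where(paired)[0].tolist(), :, :, :] \
                if not paired.all() else fake_t
            target = Tensor(batch.tgt_images[:, None])
            if feats["ms_ssim_recon"]:
                rec = recon_loss(pred_paired, target, weights,
                                 n_scales=n_scales, data_range=2.0)
            else:
                rec = l1_loss(pred_paired, target)
            g_loss = g_loss + variant.recon_weight * rec
            row["recon"] = float(rec.data)
        if feats["use_unpaired"] and batch.is_unpaired.any():
            uidx = np.where(batch.is_unpaired)[0].tolist()
            fake_u = fake_t[uidx, :, :, :]
            back = G(fake_u, yt[uidx, :], ys[uidx, :])
            cyc = l1_loss(back, Tensor(src[uidx]))
            cond = conditioning_loss(ac(fake_u), batch.tgt_labels[uidx])
            g_loss = g_loss + variant.cycle_weight * cyc + weights.lambda_c * cond
            row["cycle"] = float(cyc.data)
            row["conditioning"] = float(cond.data)
        opt_g.zero_grad()
        g_loss.backward()
        opt_g.step()
        ema.update(G)
        row["g_loss"] = float(g_loss.data)
        history.append(row)
        if progress and (it + 1) % 100 == 0:
            print(f"[gan] iter {it + 1}/{variant.iterations} "
                  f"d {row['d_loss']:.3f} g {row['g_loss']:.3f}")

    G.ema_shadow = ema.shadow
    bundle = ModelBundle(
        G=lambda img, ys_, yt_: G(img, ys_, yt_),
        F=lambda img, ys_, yt_: G(img, yt_, ys_),
        D=D, AC=ac)
    bundle.generator = G
    bundle.discriminator = D
    bundle.ema = ema
    return bundle, pd.DataFrame(history)


def _n_scales_for(image_size: int) -> int:
    """Largest usable MS-SSIM scale count for a given image side (max 5)."""
    n = 1
    while n < 5 and image_size // 2 ** n >= 11:
        n += 1
    return n


def _augment_paired(batch: Batch, rng: np.random.Generator) -> Batch:
    """Shared shift/zoom augmentation, identical for source and paired target."""
    seeds = rng.integers(0, 2 ** 31 - 1, size=len(batch.src_images))
    src = np.empty_like(batch.src_images)
    tgt = batch.tgt_images.copy() if batch.tgt_images is not None else None
    t_idx = 0
    for i, seed in enumerate(seeds):
        src[i] = augment(batch.src_images[i], seed=int(seed))
        if not batch.is_unpaired[i] and tgt is not None:
            tgt[t_idx] = augment(batch.tgt_images[t_idx], seed=int(seed))
            t_idx += 1
    return replace(batch, src_images=src, tgt_images=tgt)


def translator_from_bundle(bundle: ModelBundle, use_ema: bool = True):
    """A (image, source label, target label) -> image callable for evaluation."""
    from .networks import translate

    G: Generator = bundle.generator
    shadow = getattr(G, "ema_shadow", None)

    def _translate(image, src_label, tgt_label):
        ys = src_label.vector() if hasattr(src_label, "vector") else src_label
        yt = tgt_label.vector() if hasattr(tgt_label, "vector") else tgt_label
        if use_ema and shadow is not None:
            with nn.swap_parameters(G, shadow):
                return translate(G, image, ys, yt)
        return translate(G, image, ys, yt)

    return _translate
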