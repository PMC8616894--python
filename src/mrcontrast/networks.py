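"""Network architectures: conditioned residual U-Net generator, residual
discriminator, and the pluggable auxiliary classifier.

The generator is a U-Net of residual blocks.  Source-acquisition labels are
injected into the encoder blocks and target labels into the decoder blocks
through AdaIN; each conditioned block owns its own pair of single-layer
style projections (alpha, beta), identity-initialized so an untrained
generator is exactly label-invariant.  Projections are always built even
when a variant disables their use, so all model variants share one
parameter count and differ by wiring only.

Downsampling is by strided convolution and upsampling by nearest-neighbour
interpolation followed by convolution (avoids checkerboard artifacts).
Residual blocks use 3x3 kernels with leaky-ReLU (slope 0.2).  The
discriminator stacks six residual blocks (no normalization — compatible
with the R1 penalty) onto a single raw score.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .conditioning import StyleParams, adain

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "SmallCNNClassifier",
    "build_generator",
    "build_discriminator",
    "build_aux_classifier",
    "translate",
    "contrast_grid",
    "save_checkpoint",
    "load_checkpoint",
]

LEAKY_SLOPE = 0.2


@dataclass
class GeneratorConfig:
    encoder_filters: tuple[int, ...] = (64, 128, 256, 512)
    base_size: int = 256
    inject_source_labels: bool = True
    inject_target_labels: bool = True
    res_blocks_per_level: int = 1
    label_dim: int = 3
    global_residual: bool = True

    def __post_init__(self):
        levels = len(self.encoder_filters)
        if self.base_size % 2 ** (levels - 1):
            raise ValueError(
                f"base_size must be divisible by {2 ** (levels - 1)}")


@dataclass
class DiscriminatorConfig:
    filters: tuple[int, ...] = (64, 128, 256, 512, 512, 512)
    base_size: int = 256


def desk_generator_config(**overrides) -> GeneratorConfig:
    """Desk-scale defaults: 64x64 images, half-width filters."""
    cfg = dict(encoder_filters=(32, 64, 128, 256), base_size=64)
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


class StyleProjection(nn.Module):
    """Single affine layers mapping a label vector to (alpha, beta).

    Identity initialization (zero weights, alpha bias 1, beta bias 0) makes
    AdaIN start out as plain instance normalization.
    """

    def __init__(self, label_dim: int, n_channels: int):
        self.w_alpha = nn.Parameter(np.zeros((n_channels, label_dim)))
        self.b_alpha = nn.Parameter(np.ones(n_channels))
        self.w_beta = nn.Parameter(np.zeros((n_channels, label_dim)))
        self.b_beta = nn.Parameter(np.zeros(n_channels))

    def forward(self, label: Tensor) -> StyleParams:
        alpha = ad.add(ad.matmul(label, ad.swapaxes(self.w_alpha, 0, 1)), self.b_alpha)
        beta = ad.add(ad.matmul(label, ad.swapaxes(self.w_beta, 0, 1)), self.b_beta)
        return StyleParams(alpha=alpha, beta=beta)


class ResBlock(nn.Module):
    """Residual block with AdaIN (or plain instance norm) after each conv."""

    def __init__(self, in_ch: int, out_ch: int, label_dim: int,
                 rng: np.random.Generator, norm: bool = True):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng=rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng=rng)
        self.skip = nn.Conv2d(in_ch, out_ch, 1, rng=rng) if in_ch != out_ch else None
        self.style1 = StyleProjection(label_dim, out_ch)
        self.style2 = StyleProjection(label_dim, out_ch)
        self.norm = norm

    def _norm(self, h: Tensor, proj: StyleProjection, label: Tensor | None) -> Tensor:
        if not self.norm:
            return h
        if label is None:
            C = h.shape[1]
            style = StyleParams(alpha=np.ones((1, C), dtype=np.float32),
                                beta=np.zeros((1, C), dtype=np.float32))
        else:
            style = proj(label)
        return adain(h, style)

    def forward(self, x: Tensor, label: Tensor | None = None) -> Tensor:
        h = ad.leaky_relu(self._norm(self.conv1(x), self.style1, label), LEAKY_SLOPE)
        h = ad.leaky_relu(self._norm(self.conv2(h), self.style2, label), LEAKY_SLOPE)
        s = self.skip(x) if self.skip is not None else x
        # 1/sqrt(2) keeps activation variance flat across stacked blocks
        return ad.mul(ad.add(h, s), 1.0 / np.sqrt(2.0))


class Generator(nn.Module):
    """AdaIN-conditioned residual U-Net translating one contrast to another."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        f = config.encoder_filters
        L = config.label_dim
        self.stem = nn.Conv2d(1, f[0], 3, rng=rng)
        self.enc_blocks = [
            [ResBlock(f[i], f[i], L, rng) for _ in range(config.res_blocks_per_level)]
            for i in range(len(f))
        ]
        self.down = [nn.Conv2d(f[i], f[i + 1], 3, stride=2, rng=rng)
                     for i in range(len(f) - 1)]
        self.bottleneck = ResBlock(f[-1], f[-1], L, rng)
        self.up = [nn.Conv2d(f[i + 1], f[i], 3, rng=rng)
                   for i in range(len(f) - 1)]
        self.dec_blocks = [
            [ResBlock(2 * f[i] if j == 0 else f[i], f[i], L, rng)
             for j in range(config.res_blocks_per_level)]
            for i in range(len(f) - 1)
        ]
        self.head = nn.Conv2d(f[0], 1, 3, rng=rng, weight_scale=0.2)

    def forward(self, x: Tensor, y_source: Tensor | None = None,
                y_target: Tensor | None = None) -> Tensor:
        cfg = self.config
        x = ad.as_tensor(x)
        if x.ndim != 4:
            raise ValueError("generator expects an (B, 1, H, W) batch")
        if x.shape[2] % 2 ** (len(cfg.encoder_filters) - 1):
            raise ValueError("input size not divisible by the downsampling factor")
        ys = y_source if cfg.inject_source_labels else None
        yt = y_target if cfg.inject_target_labels else None
        ys = ad.as_tensor(ys) if ys is not None else None
        yt = ad.as_tensor(yt) if yt is not None else None

        h = self.stem(x)
        skips = []
        for i, blocks in enumerate(self.enc_blocks):
            for blk in blocks:
                h = blk(h, ys)
            if i < len(self.down):
                skips.append(h)
                h = ad.leaky_relu(self.down[i](h), LEAKY_SLOPE)
        h = self.bottleneck(h, yt)
        for i in reversed(range(len(self.up))):
            h = self.up[i](ad.upsample2_nearest(h))
            h = ad.concat([h, skips[i]], axis=1)
            for blk in self.dec_blocks[i]:
                h = blk(h, yt)
        out = self.head(h)
        if cfg.global_residual:
            out = ad.add(out, x)
        return ad.tanh(out)


class DResBlock(nn.Module):
    """Discriminator residual block with stride-2 downsampling, no norm."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=2, rng=rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng=rng)
        self.skip = nn.Conv2d(in_ch, out_ch, 1, stride=2, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = ad.leaky_relu(self.conv1(x), LEAKY_SLOPE)
        h = ad.leaky_relu(self.conv2(h), LEAKY_SLOPE)
        return ad.mul(ad.add(h, self.skip(x)), 1.0 / np.sqrt(2.0))


class Discriminator(nn.Module):
    """Residual CNN mapping an image batch to one raw score per sample."""

    def __init__(self, config: DiscriminatorConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        f = config.filters
        self.stem = nn.Conv2d(1, f[0], 3, rng=rng)
        self.blocks = [DResBlock(f[i], f[i + 1] if i + 1 < len(f) else f[i], rng)
                       for i in range(len(f))]
        self.fc = nn.Linear(f[-1], 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = ad.as_tensor(x)
        if x.ndim == 3:
            x = ad.reshape(x, (x.shape[0], 1) + x.shape[1:])
        h = ad.leaky_relu(self.stem(x), LEAKY_SLOPE)
        for blk in self.blocks:
            if min(h.shape[2], h.shape[3]) >= 2:
                h = blk(h)
        h = ad.mean(h, axis=(2, 3))
        return ad.reshape(self.fc(h), (x.shape[0],))


class SmallCNNClassifier(nn.Module):
    """Desk-scale auxiliary classifier: 4 strided conv blocks + pooled heads.

    Maps an image to (te_scaled, tr_scaled, fs_logit); the TE/TR heads are
    linear and the FS decision is ``logit > 0``.  The pooled representation
    concatenates per-channel spatial means, second moments and maxima, so
    small bright structures (e.g. unsuppressed fat, fluid pockets) are not
    washed out by global averaging; a small hidden layer sits before the
    3-way head.
    """

    def __init__(self, channels: tuple[int, ...] = (8, 16, 32, 64),
                 hidden: int = 64, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        chans = (1,) + tuple(channels)
        self.convs = [nn.Conv2d(chans[i], chans[i + 1], 3, stride=2, rng=rng)
                      for i in range(len(channels))]
        self.fc_hidden = nn.Linear(3 * channels[-1], hidden, rng=rng)
        self.fc = nn.Linear(hidden, 3, rng=rng)
        self.trained = False

    def forward(self, x: Tensor) -> Tensor:
        x = ad.as_tensor(x)
        if x.ndim == 2:
            x = ad.reshape(x, (1, 1) + x.shape)
        elif x.ndim == 3:
            x = ad.reshape(x, (x.shape[0], 1) + x.shape[1:])
        h = x
        for conv in self.convs:
            h = ad.leaky_relu(conv(h), LEAKY_SLOPE)
        pooled = ad.concat([ad.mean(h, axis=(2, 3)),
                            ad.mean(h * h, axis=(2, 3)),
                            ad.spatial_max(h)], axis=1)
        return self.fc(ad.leaky_relu(self.fc_hidden(pooled), LEAKY_SLOPE))

    def predict(self, image: np.ndarray) -> np.ndarray:
        """(te_scaled, tr_scaled, fs_logit) for a single image or batch."""
        with ad.no_grad():
            out = self.forward(Tensor(np.asarray(image, dtype=np.float32)))
        return out.data.squeeze()


def build_generator(config: GeneratorConfig | None = None,
                    seed: int = 0) -> Generator:
    config = config or GeneratorConfig()
    return Generator(config, rng=np.random.default_rng(seed))


def build_discriminator(config: DiscriminatorConfig | None = None,
                        seed: int = 0) -> Discriminator:
    config = config or DiscriminatorConfig()
    return Discriminator(config, rng=np.random.default_rng(seed))


def build_aux_classifier(backbone: str = "small_cnn", input_size: int = 64,
                         seed: int = 0) -> SmallCNNClassifier:
    if backbone == "small_cnn":
        return SmallCNNClassifier(rng=np.random.default_rng(seed))
    if backbone == "efficientnet_b3":
        raise RuntimeError(
            "the efficientnet_b3 backbone requires a deep-learning framework "
            "that is not available in this environment; use 'small_cnn'")
    raise RuntimeError(f"unknown auxiliary-classifier backbone {backbone!r}")


# --------------------------------------------------------------------------
# inference helpers
# --------------------------------------------------------------------------

def _validate_label_vec(vec) -> np.ndarray:
    arr = np.asarray(vec, dtype=np.float32)
    if arr.shape[-1] != 3:
        raise ValueError("label vector must have 3 components")
    if np.any(arr < -1e-6) or np.any(arr > 1.0 + 1e-6):
        raise ValueError(
            "labels appear unscaled; pass scale_labels(te_ms, tr_ms, fs)")
    return arr


def translate(generator: Generator, image: np.ndarray, y_source,
              y_target) -> np.ndarray:
    """Deterministic single forward pass; accepts one image or a batch."""
    img = np.asarray(image, dtype=np.float32)
    single = img.ndim == 2
    if single:
        img = img[None]
    batch = img[:, None]
    ys = np.atleast_2d(_validate_label_vec(y_source))
    yt = np.atleast_2d(_validate_label_vec(y_target))
    if ys.shape[0] == 1 and batch.shape[0] > 1:
        ys = np.repeat(ys, batch.shape[0], axis=0)
    if yt.shape[0] == 1 and batch.shape[0] > 1:
        yt = np.repeat(yt, batch.shape[0], axis=0)
    with ad.no_grad():
        out = generator(Tensor(batch), Tensor(ys), Tensor(yt)).data[:, 0]
    return out[0] if single else out


def contrast_grid(generator: Generator, image: np.ndarray, y_source,
                  te_list, tr_list, fs: int) -> np.ndarray:
    """Grid of translations, rows ordered by increasing TE, columns by TR."""
    from .conditioning import scale_labels

    te_list = sorted(float(t) for t in te_list)
    tr_list = sorted(float(t) for t in tr_list)
    if not te_list or not tr_list:
        raise ValueError("te_list and tr_list must be nonempty")
    rows = []
    for te in te_list:
        row = [translate(generator, image, y_source, scale_labels(te, tr, fs))
               for tr in tr_list]
        rows.append(np.stack(row))
    return np.stack(rows)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def save_checkpoint(path: str | Path, generator: Generator,
                    ema_shadow: dict[str, np.ndarray] | None = None,
                    extra: dict | None = None) -> None:
    """Self-contained archive: weights, config, EMA shadow, label scaling."""
    from .conditioning import TE_MAX_MS, TR_MAX_MS

    meta = {"generator_config": asdict(generator.config),
            "te_max_ms": TE_MAX_MS, "tr_max_ms": TR_MAX_MS,
            "extra": extra or {}}
    arrays = {f"gen::{k}": v for k, v in generator.state_dict().items()}
    if ema_shadow is not None:
        arrays.update({f"ema::{k}": v for k, v in ema_shadow.items()})
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path, use_ema: bool = True
                    ) -> tuple[Generator, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = GeneratorConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in meta["generator_config"].items()})
        gen = Generator(cfg)
        gen_state = {k.split("::", 1)[1]: data[k] for k in data.files
                     if k.startswith("gen::")}
        ema_state = {k.split("::", 1)[1]: data[k] for k in data.files
                     if k.startswith("ema::")}
    gen.load_state_dict(ema_state if (use_ema and ema_state) else gen_state)
    return gen, meta
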