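"""Acquisition-parameter conditioning: label scaling and AdaIN.

The generator is conditioned on the sequence parameters that determine MR
image contrast — echo time TE, repetition time TR, and the binary
fat-saturation flag FS.  TE and TR are scaled linearly to [0, 1] by the
dataset filter bounds (TE <= 50 ms, TR <= 5000 ms), and the resulting
3-vector (te_scaled, tr_scaled, fs) is injected into the network through
adaptive instance normalization:

    AdaIN(x, y) = alpha(y) * (x - mu(x)) / sigma(x) + beta(y)

where mu and sigma are per-sample, per-channel spatial moments of the
feature map x and alpha, beta are single affine layers of the label vector
(one pair per injection site).  At identity initialization (W = 0,
b_alpha = 1, b_beta = 0) AdaIN reduces to plain instance normalization, so
an untrained conditioned generator behaves exactly like an unconditioned
one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

TE_MAX_MS = 50.0
TR_MAX_MS = 5000.0
ADAIN_EPSILON = 1e-5


@dataclass(frozen=True)
class AcquisitionLabel:
    """One acquisition condition: TE (ms), TR (ms) and the FS flag."""

    te_ms: float
    tr_ms: float
    fs: int

    def __post_init__(self):
        if not (0.0 < self.te_ms <= TE_MAX_MS):
            raise ValueError(f"TE must lie in (0, {TE_MAX_MS}] ms, got {self.te_ms}")
        if not (0.0 < self.tr_ms <= TR_MAX_MS):
            raise ValueError(f"TR must lie in (0, {TR_MAX_MS}] ms, got {self.tr_ms}")
        if self.fs not in (0, 1):
            raise ValueError("fs flag must be 0 or 1")

    @property
    def te_scaled(self) -> float:
        return self.te_ms / TE_MAX_MS

    @property
    def tr_scaled(self) -> float:
        return self.tr_ms / TR_MAX_MS

    def vector(self) -> np.ndarray:
        return np.array([self.te_scaled, self.tr_scaled, float(self.fs)],
                        dtype=np.float32)


@dataclass
class StyleParams:
    """Per-channel scale (alpha) and bias (beta) at one injection site."""

    alpha: np.ndarray | Tensor
    beta: np.ndarray | Tensor

    def n_channels(self) -> int:
        a = self.alpha.data if isinstance(self.alpha, Tensor) else np.asarray(self.alpha)
        return a.shape[-1]


@dataclass
class FeatureStats:
    """Per-sample, per-channel spatial moments of a feature map."""

    mean: np.ndarray
    sd: np.ndarray


def scale_labels(te_ms: float, tr_ms: float, fs: int,
                 te_max: float = TE_MAX_MS, tr_max: float = TR_MAX_MS) -> np.ndarray:
    """Scale (TE, TR, FS) to the [0, 1]-valued conditioning vector."""
    te_ms = np.asarray(te_ms, dtype=np.float64)
    tr_ms = np.asarray(tr_ms, dtype=np.float64)
    if np.any(te_ms <= 0) or np.any(te_ms > te_max):
        raise ValueError(f"TE out of range (0, {te_max}]")
    if np.any(tr_ms <= 0) or np.any(tr_ms > tr_max):
        raise ValueError(f"TR out of range (0, {tr_max}]")
    fs_arr = np.asarray(fs, dtype=np.float64)
    if not np.all(np.isin(fs_arr, (0.0, 1.0))):
        raise ValueError("fs flag must be 0 or 1")
    return np.stack(np.broadcast_arrays(te_ms / te_max, tr_ms / tr_max, fs_arr),
                    axis=-1)


def unscale_labels(vec: np.ndarray, te_max: float = TE_MAX_MS,
                   tr_max: float = TR_MAX_MS) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Invert :func:`scale_labels`; FS is returned as the raw third component."""
    vec = np.asarray(vec, dtype=np.float64)
    return vec[..., 0] * te_max, vec[..., 1] * tr_max, vec[..., 2]


def feature_stats(features, epsilon: float = ADAIN_EPSILON) -> FeatureStats:
    """Spatial moments (per sample and channel) of an NCHW feature batch."""
    x = features.data if isinstance(features, Tensor) else np.asarray(features)
    mu = x.mean(axis=(2, 3))
    sd = np.sqrt(x.var(axis=(2, 3)) + epsilon)
    return FeatureStats(mean=mu, sd=sd)


def adain(features, style: StyleParams, epsilon: float = ADAIN_EPSILON):
    """Adaptive instance normalization of an NCHW feature batch.

    Each channel of each sample is normalized by its own spatial mean and
    (epsilon-stabilized) standard deviation, then scaled by ``style.alpha``
    and shifted by ``style.beta``.  Accepts numpy arrays or autodiff tensors;
    alpha/beta may be per-channel ``(C,)`` or per-sample ``(B, C)``.
    """
    was_array = not isinstance(features, Tensor)
    x = ad.as_tensor(features)
    if x.ndim != 4:
        raise ValueError("adain expects an NCHW feature batch")
    B, C, H, W = x.shape
    alpha = ad.as_tensor(style.alpha)
    beta = ad.as_tensor(style.beta)
    if alpha.shape[-1] != C or beta.shape[-1] != C:
        raise ValueError(
            f"style has {alpha.shape[-1]} channels, features have {C}")
    mu = ad.mean(x, axis=(2, 3), keepdims=True)
    var = ad.mean((x - mu) * (x - mu), axis=(2, 3), keepdims=True)
    sd = ad.sqrt(var + epsilon)
    normalized = (x - mu) / sd
    a4 = ad.reshape(alpha, (-1, C, 1, 1))
    b4 = ad.reshape(beta, (-1, C, 1, 1))
    out = a4 * normalized + b4
    return out.data if was_array else out


def style_projection(label_vector, n_channels: int,
                     weights: dict[str, np.ndarray] | None = None) -> StyleParams:
    """Project a 3-vector label onto per-channel (alpha, beta).

    One affine map each, no hidden layers.  ``weights`` holds ``w_alpha``,
    ``b_alpha``, ``w_beta``, ``b_beta`` with ``w_*`` of shape (n_channels, 3);
    when omitted, identity-initialized weights (alpha = 1, beta = 0 for every
    label) are used.
    """
    lv = label_vector.data if isinstance(label_vector, Tensor) else np.asarray(label_vector)
    if lv.shape[-1] != 3:
        raise ValueError("label vector must have 3 components (te, tr, fs)")
    if weights is None:
        weights = identity_style_weights(n_channels)
    w_a = np.asarray(weights["w_alpha"], dtype=lv.dtype)
    w_b = np.asarray(weights["w_beta"], dtype=lv.dtype)
    alpha = lv @ w_a.T + np.asarray(weights["b_alpha"], dtype=lv.dtype)
    beta = lv @ w_b.T + np.asarray(weights["b_beta"], dtype=lv.dtype)
    return StyleParams(alpha=alpha, beta=beta)


def identity_style_weights(n_channels: int) -> dict[str, np.ndarray]:
    """Weights for which alpha(y) = 1 and beta(y) = 0 for every label y."""
    return {
        "w_alpha": np.zeros((n_channels, 3), dtype=np.float32),
        "b_alpha": np.ones(n_channels, dtype=np.float32),
        "w_beta": np.zeros((n_channels, 3), dtype=np.float32),
        "b_beta": np.zeros(n_channels, dtype=np.float32),
    }
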