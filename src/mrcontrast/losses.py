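"""Training objectives.

* Weighted reconstruction loss  L = omega * (1 - MS-SSIM) + (1 - omega) * L1
  with omega = 0.84 balancing the two terms.
* Non-saturating adversarial loss in its numerically stable softplus form,
  with the R1 gradient penalty (gamma = 1) on real samples.
* Cycle-consistency loss (L1 of the round trip in both directions).
* Conditioning loss of the auxiliary classifier: MSE over scaled TE and TR
  (averaged) plus binary cross-entropy over the FS flag, weighted by
  lambda_c = 10 in the generator objective.

All losses accept numpy arrays or autodiff tensors and return an autodiff
scalar, so they serve both as training objectives and as plain functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .metrics import SSIM_K1, SSIM_K2, gaussian_window

__all__ = [
    "LossWeights",
    "ModelBundle",
    "l1_loss",
    "ms_ssim",
    "recon_loss",
    "nonsat_gan_losses",
    "r1_penalty",
    "cycle_loss",
    "conditioning_loss",
    "bce_with_logits",
    "MS_SSIM_WEIGHTS",
]

#: Per-scale exponents of the 5-scale MS-SSIM (Wang et al. defaults).
MS_SSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

_WINDOW_SIZE = 11


@dataclass
class LossWeights:
    """omega: MS-SSIM share of the reconstruction loss; gamma_r1: R1
    coefficient; lambda_c: conditioning-loss weight."""

    omega: float = 0.84
    gamma_r1: float = 1.0
    lambda_c: float = 10.0

    def __post_init__(self):
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if self.gamma_r1 < 0 or self.lambda_c < 0:
            raise ValueError("gamma_r1 and lambda_c must be >= 0")


@dataclass
class ModelBundle:
    """Generators for both directions plus discriminator and optional AC.

    A single acquisition-conditioned generator may serve as both G and F by
    being invoked with swapped source/target labels; in that case both
    callables close over the same network.
    """

    G: Callable | None = None
    F: Callable | None = None
    D: Callable | None = None
    AC: Callable | None = None


def _as_batch(x) -> Tensor:
    t = ad.as_tensor(x)
    if t.ndim == 2:
        t = ad.reshape(t, (1, 1) + t.shape)
    elif t.ndim == 3:
        t = ad.reshape(t, (t.shape[0], 1) + t.shape[1:])
    return t


def l1_loss(x, x_prime) -> Tensor:
    """Mean absolute difference over all pixels and batch entries."""
    x, x_prime = ad.as_tensor(x), ad.as_tensor(x_prime)
    if x.shape != x_prime.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    diff = x - x_prime
    sign = Tensor(np.sign(diff.data))
    return ad.mean(diff * sign)


def _min_side(n_scales: int) -> int:
    return _WINDOW_SIZE * 2 ** (n_scales - 1)


def ms_ssim(x, x_prime, n_scales: int = 5, data_range: float | None = None) -> Tensor:
    """Multi-scale SSIM.

    Contrast-structure terms are averaged at each of ``n_scales`` dyadic
    scales (2x average pooling between scales) and the luminance term enters
    at the coarsest scale only; the terms are combined with the standard
    exponents, renormalized to sum to one when fewer than five scales are
    used (small images).  ``data_range`` defaults to the joint value range
    of the pair, matching the metrics module's SSIM.
    """
    x, x_prime = _as_batch(x), _as_batch(x_prime)
    if x.shape != x_prime.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_prime.shape}")
    if not 1 <= n_scales <= len(MS_SSIM_WEIGHTS):
        raise ValueError(f"n_scales must lie in [1, {len(MS_SSIM_WEIGHTS)}]")
    side = min(x.shape[2], x.shape[3])
    if side < _min_side(n_scales):
        raise ValueError(
            f"image side {side} too small for {n_scales} scales; "
            f"need at least {_min_side(n_scales)} pixels")
    if data_range is None:
        data_range = float(max(x.data.max(), x_prime.data.max()) -
                           min(x.data.min(), x_prime.data.min())) or 1.0
    c1 = (SSIM_K1 * data_range) ** 2
    c2 = (SSIM_K2 * data_range) ** 2
    weights = np.asarray(MS_SSIM_WEIGHTS[:n_scales], dtype=np.float64)
    weights = weights / weights.sum()

    window = Tensor(gaussian_window()[None, None].astype(x.dtype))
    result = None
    for scale in range(n_scales):
        ssim_mean, cs_mean = _ssim_parts(x, x_prime, window, c1, c2)
        term = ssim_mean if scale == n_scales - 1 else cs_mean
        term = ad.maximum_const(term, 1e-6) ** float(weights[scale])
        result = term if result is None else result * term
        if scale < n_scales - 1:
            x = ad.avg_pool2(x)
            x_prime = ad.avg_pool2(x_prime)
    return result


def _ssim_parts(x: Tensor, y: Tensor, window: Tensor, c1: float, c2: float):
    """Batch means of the windowed SSIM map and contrast-structure map."""

    def filt(a):
        return ad.conv2d(a, window, stride=1, padding=0)

    mu_x, mu_y = filt(x), filt(y)
    sigma_x2 = filt(x * x) - mu_x * mu_x
    sigma_y2 = filt(y * y) - mu_y * mu_y
    sigma_xy = filt(x * y) - mu_x * mu_y
    cs_map = (sigma_xy * 2.0 + c2) / (sigma_x2 + sigma_y2 + c2)
    lum_map = (mu_x * mu_y * 2.0 + c1) / (mu_x * mu_x + mu_y * mu_y + c1)
    return ad.mean(lum_map * cs_map), ad.mean(cs_map)


def recon_loss(x, x_prime, weights: LossWeights | None = None,
               n_scales: int = 5, data_range: float | None = None) -> Tensor:
    """omega * (1 - MS-SSIM) + (1 - omega) * L1."""
    weights = weights or LossWeights()
    l1 = l1_loss(x, x_prime)
    if weights.omega == 0.0:
        return l1
    msv = ms_ssim(x, x_prime, n_scales=n_scales, data_range=data_range)
    return weights.omega * (1.0 - msv) + (1.0 - weights.omega) * l1


def nonsat_gan_losses(d_real, d_fake) -> tuple[Tensor, Tensor]:
    """Non-saturating GAN losses from raw (pre-sigmoid) discriminator scores.

    Returns ``(g_loss, d_loss)`` with
    d_loss = E[softplus(-D(real))] + E[softplus(D(fake))] and
    g_loss = E[softplus(-D(fake))].
    """
    d_real, d_fake = ad.as_tensor(d_real), ad.as_tensor(d_fake)
    d_loss = ad.mean(ad.softplus(-d_real)) + ad.mean(ad.softplus(d_fake))
    g_loss = ad.mean(ad.softplus(-d_fake))
    return g_loss, d_loss


def r1_penalty(discriminator: Callable, real_batch,
               weights: LossWeights | None = None) -> Tensor:
    """(gamma/2) * E[ || grad_x D(x) ||^2 ] on real samples.

    The gradient is taken with ``create_graph=True``, so the returned scalar
    can be backpropagated into the discriminator parameters (double
    backprop).
    """
    weights = weights or LossWeights()
    x = Tensor(np.asarray(real_batch), requires_grad=True)
    scores = discriminator(x)
    (g,) = ad.grad(ad.tsum(scores), [x], create_graph=True)
    per_sample = ad.tsum(g * g, axis=tuple(range(1, g.ndim)))
    return (weights.gamma_r1 / 2.0) * ad.mean(per_sample)


def cycle_loss(bundle: ModelBundle, g_batch, t_batch) -> Tensor:
    """E||G(F(g)) - g||_1 + E||F(G(t)) - t||_1.

    ``G`` maps domain A to B and ``F`` maps B back to A; with a single
    conditioned generator the two are the same network invoked with swapped
    source/target labels.
    """
    if bundle.G is None or bundle.F is None:
        raise RuntimeError("cycle training requires both generator directions")
    g = ad.as_tensor(g_batch)
    t = ad.as_tensor(t_batch)
    return l1_loss(bundle.G(bundle.F(g)), g) + l1_loss(bundle.F(bundle.G(t)), t)


def bce_with_logits(logit, target) -> Tensor:
    """Elementwise binary cross-entropy from raw logits (stable form)."""
    logit = ad.as_tensor(logit)
    target = ad.as_tensor(target)
    return ad.softplus(logit) - logit * target


def conditioning_loss(ac_prediction, target_label) -> Tensor:
    """MSE over scaled TE and TR (averaged) plus BCE over the FS flag.

    ``ac_prediction`` is a (B, 3) batch or 3-vector of
    (te_scaled, tr_scaled, fs_logit); ``target_label`` the matching scaled
    label vectors.  The lambda_c weighting is applied by the caller when the
    loss enters the generator objective.
    """
    pred = ad.as_tensor(ac_prediction)
    target = np.asarray(target_label.data if isinstance(target_label, Tensor)
                        else target_label, dtype=np.float64)
    if pred.ndim == 1:
        pred = ad.reshape(pred, (1, 3))
        target = target.reshape(1, 3)
    if pred.shape[-1] != 3 or target.shape != pred.shape:
        raise ValueError("prediction and label must both be (B, 3)")
    te_err = pred[:, 0:1] - target[:, 0:1]
    tr_err = pred[:, 1:2] - target[:, 1:2]
    mse = ad.mean(te_err * te_err + tr_err * tr_err) * 0.5
    bce = ad.mean(bce_with_logits(pred[:, 2:3], target[:, 2:3]))
    return mse + bce
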