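"""Training objectives: closed forms, oracles, invariants."""

import numpy as np
import pytest

from mrcontrast import autodiff as ad
from mrcontrast.losses import (LossWeights, ModelBundle, bce_with_logits,
                               conditioning_loss, cycle_loss, l1_loss, ms_ssim,
                               nonsat_gan_losses, r1_penalty, recon_loss)
from mrcontrast.metrics import ssim

from _oracles import ms_ssim_single_scale_loops


class TestL1:
    def test_closed_forms(self):
        x = np.zeros((1, 2, 2))
        assert l1_loss(x, x).item() == 0.0
        assert l1_loss(x, x + 0.3).item() == pytest.approx(0.3)
        diff = np.array([[0.1, -0.2], [0.0, 0.3]])
        assert l1_loss(np.zeros((2, 2)), diff).item() == pytest.approx(0.15)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMsSsim:
    def test_perfect_and_symmetric(self, rng):
        x = rng.uniform(-1, 1, size=(2, 32, 32))
        y = x + rng.normal(0, 0.2, size=x.shape)
        assert ms_ssim(x, x, n_scales=2).item() == pytest.approx(1.0)
        assert ms_ssim(x, y, n_scales=2).item() == \
            pytest.approx(ms_ssim(y, x, n_scales=2).item(), abs=1e-12)

    def test_single_scale_matches_loop_oracle(self, rng):
        x = rng.uniform(-1, 1, size=(16, 16))
        y = x + rng.normal(0, 0.25, size=x.shape)
        ours = ms_ssim(x, y, n_scales=1).item()
        assert ours == pytest.approx(ms_ssim_single_scale_loops(x, y), abs=1e-6)

    def test_single_scale_matches_metrics_ssim(self, rng):
        """Cross-module consistency: the loss and the metric share windowing."""
        x = rng.uniform(-1, 1, size=(24, 24))
        y = np.clip(x + rng.normal(0, 0.3, size=x.shape), -1, 1)
        assert ms_ssim(x, y, n_scales=1).item() == \
            pytest.approx(ssim(x, y, windowed=True), abs=1e-6)

    def test_too_small_image_raises_with_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            ms_ssim(np.zeros((16, 16)), np.zeros((16, 16)), n_scales=3)

    def test_noise_monotonicity(self, rng):
        x = rng.uniform(-1, 1, size=(48, 48))
        noise = np.random.default_rng(7).normal(size=x.shape)
        vals = [ms_ssim(x, x + sd * noise, n_scales=2, data_range=2.0).item()
                for sd in (0.05, 0.1, 0.2, 0.4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestRecon:
    def test_zero_on_identical(self, rng):
        x = rng.uniform(-1, 1, size=(1, 32, 32))
        assert recon_loss(x, x, n_scales=2).item() == pytest.approx(0.0, abs=1e-12)

    def test_omega_zero_is_l1(self, rng):
        x = rng.uniform(-1, 1, size=(1, 32, 32))
        y = x + 0.1
        w = LossWeights(omega=0.0)
        assert recon_loss(x, y, w).item() == pytest.approx(l1_loss(x, y).item())

    def test_weighted_combination(self, rng):
        x = rng.uniform(-1, 1, size=(1, 32, 32))
        y = np.clip(x + rng.normal(0, 0.2, size=x.shape), -1, 1)
        a = l1_loss(x, y).item()
        b = ms_ssim(x, y, n_scales=2).item()
        got = recon_loss(x, y, LossWeights(omega=0.84), n_scales=2).item()
        assert got == pytest.approx(0.84 * (1 - b) + 0.16 * a, abs=1e-9)

    def test_nonnegative(self, rng):
        x = rng.uniform(-1, 1, size=(1, 32, 32))
        y = rng.uniform(-1, 1, size=(1, 32, 32))
        assert recon_loss(x, y, n_scales=2).item() >= 0


class TestNonsatGan:
    def test_zero_scores(self):
        g, d = nonsat_gan_losses(np.zeros(3), np.zeros(3))
        assert d.item() == pytest.approx(2 * np.log(2))
        assert g.item() == pytest.approx(np.log(2))

    def test_perfect_discriminator_limit(self):
        g, d = nonsat_gan_losses(np.full(2, 50.0), np.full(2, -50.0))
        assert d.item() == pytest.approx(0.0, abs=1e-12)

    def test_softplus_by_hand(self):
        g, d = nonsat_gan_losses(np.array([1.0]), np.array([-1.0]))
        sp = np.log1p(np.exp(-1.0))
        assert d.item() == pytest.approx(2 * sp)
        assert g.item() == pytest.approx(np.log1p(np.exp(1.0)))


class TestR1:
    def test_constant_discriminator_zero(self, rng):
        r1 = r1_penalty(lambda x: ad.mul(ad.tsum(x, axis=(1, 2, 3)), 0.0),
                        rng.normal(size=(2, 1, 4, 4)))
        assert r1.item() == 0.0

    def test_linear_discriminator_closed_form(self, rng):
        w = rng.normal(size=(1, 1, 6, 6))

        def lin(x):
            return ad.tsum(x * ad.Tensor(w), axis=(1, 2, 3))

        batch = rng.normal(size=(4, 1, 6, 6))
        assert r1_penalty(lin, batch).item() == \
            pytest.approx(0.5 * float((w ** 2).sum()), abs=1e-6)
        # doubling gamma doubles the penalty
        double = r1_penalty(lin, batch, LossWeights(gamma_r1=2.0)).item()
        assert double == pytest.approx(float((w ** 2).sum()), abs=1e-6)

    def test_penalty_backprops_to_parameters(self, rng):
        """Double backprop: the R1 penalty must produce parameter gradients."""
        from mrcontrast.networks import Discriminator, DiscriminatorConfig

        disc = Discriminator(DiscriminatorConfig(filters=(4, 8), base_size=8),
                             rng=np.random.default_rng(0))
        r1 = r1_penalty(disc, rng.normal(size=(2, 1, 8, 8)).astype(np.float32))
        r1.backward()
        norms = [float(np.abs(p.grad.data).sum()) for p in disc.parameters()
                 if p.grad is not None]
        assert norms and any(n > 0 for n in norms)


class TestCycle:
    def test_identity_generators(self, rng):
        bundle = ModelBundle(G=lambda x: x, F=lambda x: x)
        g = rng.normal(size=(2, 1, 8, 8))
        t = rng.normal(size=(2, 1, 8, 8))
        assert cycle_loss(bundle, g, t).item() == 0.0

    def test_constant_offset_expansion(self, rng):
        c = 0.25
        bundle = ModelBundle(G=lambda x: x + c, F=lambda x: x)
        g = rng.normal(size=(1, 1, 4, 4))
        t = rng.normal(size=(1, 1, 4, 4))
        # G(F(g)) - g = c and F(G(t)) - t = c -> loss 2c
        assert cycle_loss(bundle, g, t).item() == pytest.approx(2 * c)

    def test_symmetric_under_domain_swap(self, rng):
        bundle = ModelBundle(G=lambda x: x * 0.9, F=lambda x: x + 0.1)
        swapped = ModelBundle(G=bundle.F, F=bundle.G)
        g = rng.normal(size=(1, 1, 4, 4))
        t = rng.normal(size=(1, 1, 4, 4))
        assert cycle_loss(bundle, g, t).item() == \
            pytest.approx(cycle_loss(swapped, t, g).item())

    def test_missing_direction_rejected(self, rng):
        with pytest.raises(RuntimeError):
            cycle_loss(ModelBundle(G=lambda x: x), np.zeros((1, 1, 4, 4)),
                       np.zeros((1, 1, 4, 4)))


class TestConditioningLoss:
    def test_perfect_prediction(self):
        pred = np.array([0.6, 0.5, 100.0])
        target = np.array([0.6, 0.5, 1.0])
        assert conditioning_loss(pred, target).item() == pytest.approx(0.0, abs=1e-9)

    def test_mse_mean_convention(self):
        pred = np.array([0.6, 0.7, 100.0])
        target = np.array([0.5, 0.5, 1.0])
        # (0.01 + 0.04) / 2 with the BCE term vanishing
        assert conditioning_loss(pred, target).item() == \
            pytest.approx(0.025, abs=1e-9)

    def test_zero_logit_gives_ln2(self):
        for fs in (0.0, 1.0):
            val = conditioning_loss(np.array([0.5, 0.5, 0.0]),
                                    np.array([0.5, 0.5, fs])).item()
            assert val == pytest.approx(np.log(2))

    def test_bce_with_logits_stable(self):
        assert bce_with_logits(np.array([500.0]), np.array([1.0])).data[0] == \
            pytest.approx(0.0, abs=1e-12)
        assert np.isfinite(bce_with_logits(np.array([-500.0]), np.array([1.0])).data[0])
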