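"""Generator / discriminator / auxiliary-classifier contracts."""

import numpy as np
import pytest

from mrcontrast import autodiff as ad
from mrcontrast.conditioning import scale_labels
from mrcontrast.networks import (Discriminator, DiscriminatorConfig, Generator,
                                 GeneratorConfig, build_aux_classifier,
                                 build_discriminator, build_generator,
                                 contrast_grid, load_checkpoint,
                                 save_checkpoint, translate)

from _oracles import numeric_gradient

SMALL_GEN = GeneratorConfig(encoder_filters=(4, 8, 16), base_size=32)


@pytest.fixture(scope="module")
def small_gen():
    return build_generator(SMALL_GEN, seed=1)


def _labels(n, te=30.0, tr=2500.0, fs=0):
    return np.tile(scale_labels(te, tr, fs), (n, 1)).astype(np.float32)


class TestGenerator:
    def test_output_shape_and_bounds(self, small_gen, rng):
        for size in (32, 64):
            x = rng.normal(size=(2, 1, size, size)).astype(np.float32)
            with ad.no_grad():
                out = small_gen(ad.Tensor(x), ad.Tensor(_labels(2)),
                                ad.Tensor(_labels(2, fs=1))).data
            assert out.shape == x.shape
            assert out.min() >= -1.0 and out.max() <= 1.0

    def test_indivisible_size_rejected(self, small_gen, rng):
        x = rng.normal(size=(1, 1, 30, 30)).astype(np.float32)
        with pytest.raises(ValueError):
            small_gen(ad.Tensor(x), None, None)

    def test_label_invariant_at_identity_init(self, small_gen, rng):
        x = rng.normal(size=(2, 1, 32, 32)).astype(np.float32)
        with ad.no_grad():
            a = small_gen(ad.Tensor(x), ad.Tensor(_labels(2, 10, 1000, 0)),
                          ad.Tensor(_labels(2, 10, 1000, 0))).data
            b = small_gen(ad.Tensor(x), ad.Tensor(_labels(2, 45, 4500, 1)),
                          ad.Tensor(_labels(2, 45, 4500, 1))).data
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_invariant_across_variants(self):
        counts = set()
        for src, tgt in [(False, False), (False, True), (True, True)]:
            cfg = GeneratorConfig(encoder_filters=(4, 8), base_size=32,
                                  inject_source_labels=src,
                                  inject_target_labels=tgt)
            counts.add(build_generator(cfg, seed=0).n_parameters())
        assert len(counts) == 1

    def test_forward_finite(self, small_gen, rng):
        x = rng.uniform(-1, 1, size=(2, 1, 32, 32)).astype(np.float32)
        with ad.no_grad():
            out = small_gen(ad.Tensor(x), ad.Tensor(_labels(2)),
                            ad.Tensor(_labels(2))).data
        assert np.isfinite(out).all()


class TestDiscriminator:
    def test_scores_per_sample(self, rng):
        disc = build_discriminator(DiscriminatorConfig(filters=(4, 8, 8)), seed=2)
        x = rng.normal(size=(5, 1, 16, 16)).astype(np.float32)
        assert disc(ad.Tensor(x)).shape == (5,)

    def test_default_has_six_blocks(self):
        disc = build_discriminator(seed=0)
        assert len(disc.blocks) == 6

    def test_gradient_exists_and_matches_finite_differences(self, rng):
        disc = Discriminator(DiscriminatorConfig(filters=(2, 4), base_size=8),
                             rng=np.random.default_rng(3))
        x = rng.normal(size=(1, 1, 8, 8)).astype(np.float64)
        t = ad.Tensor(x, requires_grad=True)
        disc(t).sum().backward()
        analytic = t.grad.data
        assert np.isfinite(analytic).all()

        def f(xv):
            with ad.no_grad():
                return float(disc(ad.Tensor(xv)).sum().data)

        # spot-check a few coordinates with central differences
        numeric = numeric_gradient(f, x[:, :, :2, :2].copy() * 0 + x[:, :, :2, :2])
        full_numeric = np.zeros_like(x)
        for i in range(2):
            for j in range(2):
                xp = x.copy(); xp[0, 0, i, j] += 1e-4
                xm = x.copy(); xm[0, 0, i, j] -= 1e-4
                full_numeric[0, 0, i, j] = (f(xp) - f(xm)) / 2e-4
        np.testing.assert_allclose(analytic[0, 0, :2, :2],
                                   full_numeric[0, 0, :2, :2],
                                   rtol=1e-3, atol=1e-5)


class TestAuxClassifier:
    def test_output_is_three_vector(self, rng):
        ac = build_aux_classifier("small_cnn")
        out = ac.predict(rng.normal(size=(32, 32)).astype(np.float32))
        assert out.shape == (3,)

    def test_fs_decision_convention(self):
        assert (1.5 > 0) and not (-0.5 > 0)  # decision is logit > 0

    def test_unknown_and_unavailable_backbones(self):
        with pytest.raises(RuntimeError):
            build_aux_classifier("efficientnet_b3")
        with pytest.raises(RuntimeError):
            build_aux_classifier("resnet50")


class TestTranslate:
    def test_deterministic_and_batch_consistent(self, small_gen, rng):
        img = rng.uniform(-1, 1, size=(32, 32))
        ys, yt = scale_labels(30, 2500, 0), scale_labels(40, 3000, 1)
        a = translate(small_gen, img, ys, yt)
        b = translate(small_gen, img, ys, yt)
        np.testing.assert_array_equal(a, b)
        batch = translate(small_gen, np.stack([img, img]), ys, yt)
        np.testing.assert_allclose(batch[0], a, atol=1e-6)
        np.testing.assert_allclose(batch[1], a, atol=1e-6)

    def test_raw_labels_rejected(self, small_gen, rng):
        img = rng.uniform(-1, 1, size=(32, 32))
        with pytest.raises(ValueError):
            translate(small_gen, img, np.array([30.0, 2500.0, 0.0]),
                      scale_labels(40, 3000, 1))


class TestContrastGrid:
    def test_shape_and_single_cell(self, small_gen, rng):
        img = rng.uniform(-1, 1, size=(32, 32))
        ys = scale_labels(30, 2500, 0)
        grid = contrast_grid(small_gen, img, ys, [10, 30, 45], [1000, 3000], 0)
        assert grid.shape == (3, 2, 32, 32)
        single = contrast_grid(small_gen, img, ys, [30], [3000], 0)
        np.testing.assert_allclose(
            single[0, 0], translate(small_gen, img, ys, scale_labels(30, 3000, 0)))


class TestCheckpoint:
    def test_round_trip(self, small_gen, rng, tmp_path):
        path = tmp_path / "ckpt.npz"
        shadow = {k: v + 1.0 for k, v in small_gen.state_dict().items()}
        save_checkpoint(path, small_gen, ema_shadow=shadow, extra={"variant": 3})
        loaded_ema, meta = load_checkpoint(path, use_ema=True)
        loaded_raw, _ = load_checkpoint(path, use_ema=False)
        assert meta["extra"]["variant"] == 3
        k = next(iter(shadow))
        np.testing.assert_allclose(loaded_ema.state_dict()[k], shadow[k])
        np.testing.assert_allclose(loaded_raw.state_dict()[k],
                                   small_gen.state_dict()[k])
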