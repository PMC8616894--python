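"""NMSE / PSNR / SSIM and the evaluation harnesses."""

import numpy as np
import pytest

from mrcontrast.conditioning import AcquisitionLabel
from mrcontrast.curation import ImagePair
from mrcontrast.metrics import (compare_models, evaluate_conditioning,
                                evaluate_reconstruction, nmse, psnr, ssim)

from _oracles import nmse_loops, psnr_loops, ssim_global_loops, ssim_windowed_loops


class TestNmse:
    def test_basic_values(self):
        x = np.array([[1.0, 2.0]])
        assert nmse(x, x) == 0.0
        assert nmse(x, np.zeros_like(x)) == 1.0
        assert nmse(x, np.array([[2.0, 2.0]])) == pytest.approx(1 / 5)

    def test_zero_truth_rejected(self):
        with pytest.raises(ZeroDivisionError):
            nmse(np.zeros((2, 2)), np.ones((2, 2)))

    def test_asymmetric(self, rng):
        x = rng.uniform(0.5, 1, size=(8, 8))
        y = rng.uniform(0.5, 1, size=(8, 8))
        assert nmse(x, y) != pytest.approx(nmse(y, x))


class TestPsnr:
    def test_twenty_db_example(self):
        # MSE 0.04 against joint range 2 -> 10 log10(4 / 0.04) = 20 dB
        x = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])
        y = x - 0.2 * np.sign(x)  # shift toward zero: range stays [-1, 1]
        assert psnr(x, y) == pytest.approx(20.0)

    def test_halving_mse_adds_3db(self, rng):
        # interior values + pinned extremes keep the joint range at exactly 2
        x = rng.uniform(-0.8, 0.8, size=(16, 16))
        noise = rng.normal(0, 0.05, size=x.shape)
        x[0, 0], x[0, 1] = -1.0, 1.0
        noise[0, 0] = noise[0, 1] = 0.0
        noise = np.clip(noise, -0.15, 0.15)
        p1 = psnr(x, x + noise)
        p2 = psnr(x, x + noise / np.sqrt(2))
        assert p2 - p1 == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_identical_images_inf_with_warning(self):
        x = np.ones((4, 4))
        with pytest.warns(UserWarning):
            assert psnr(x, x) == np.inf

    def test_symmetric(self, rng):
        x = rng.uniform(size=(8, 8))
        y = rng.uniform(size=(8, 8))
        assert psnr(x, y) == pytest.approx(psnr(y, x))


class TestSsim:
    def test_perfect_similarity(self, rng):
        x = rng.uniform(-1, 1, size=(16, 16))
        assert ssim(x, x) == pytest.approx(1.0)
        assert ssim(x, x, windowed=False) == pytest.approx(1.0)

    def test_global_formula_on_toy(self):
        x = np.array([[1.0, -1.0], [-1.0, 1.0]])  # zero mean
        val = ssim(x, -x, windowed=False)
        assert val == pytest.approx(ssim_global_loops(x, -x))
        assert val < 0

    def test_windowed_matches_scalar_loops(self, rng):
        x = rng.uniform(-1, 1, size=(16, 16))
        y = x + rng.normal(0, 0.2, size=x.shape)
        assert ssim(x, y) == pytest.approx(ssim_windowed_loops(x, y), abs=1e-6)

    def test_windowed_matches_skimage(self, rng):
        from skimage.metrics import structural_similarity

        x = rng.uniform(-1, 1, size=(32, 32))
        y = x + rng.normal(0, 0.3, size=x.shape)
        rng_joint = max(x.max(), y.max()) - min(x.min(), y.min())
        ref = structural_similarity(x, y, gaussian_weights=True, sigma=1.5,
                                    use_sample_covariance=False,
                                    data_range=rng_joint)
        # skimage averages over the full (edge-padded) map, this package over
        # the valid region only; on smooth noise they agree closely
        assert ssim(x, y) == pytest.approx(ref, abs=0.02)

    def test_symmetric(self, rng):
        x = rng.uniform(size=(16, 16))
        y = rng.uniform(size=(16, 16))
        assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)

    def test_windowed_equals_global_on_constant_statistics(self):
        x = np.tile(np.array([[0.0, 1.0], [1.0, 0.0]]), (8, 8))
        y = 1.0 - x
        assert ssim(x, y) == pytest.approx(ssim(x, y, windowed=False), abs=1e-9)

    def test_noise_monotonicity(self, rng):
        x = rng.uniform(-1, 1, size=(24, 24))
        vals = []
        for sd in (0.05, 0.1, 0.2, 0.4):
            noise = np.random.default_rng(99).normal(0, 1, size=x.shape)
            vals.append(ssim(x, x + sd * noise))
        assert all(a > b for a, b in zip(vals, vals[1:]))


def _toy_pairs(n=4, rng=None, identical=False):
    rng = rng or np.random.default_rng(0)
    pairs = []
    for i in range(n):
        src = rng.uniform(-1, 1, size=(16, 16))
        tgt = src.copy() if identical else np.clip(src + rng.normal(0, 0.3, src.shape), -1, 1)
        pairs.append(ImagePair(
            source_image=src, source_label=AcquisitionLabel(30.0, 2500.0, 0),
            target_image=tgt, target_label=AcquisitionLabel(40.0, 3000.0, 1),
            pair_key=f"p{i}"))
    return pairs


class TestEvaluateReconstruction:
    def test_identity_on_self_pairs(self):
        report = evaluate_reconstruction(_toy_pairs(identical=True),
                                         lambda img, ys, yt: img)
        assert (report.per_pair["nmse"] == 0).all()
        np.testing.assert_allclose(report.per_pair["ssim"], 1.0, atol=1e-9)

    def test_identity_on_contrasting_pairs_positive_nmse(self, rng):
        report = evaluate_reconstruction(_toy_pairs(rng=rng),
                                         lambda img, ys, yt: img)
        assert report.aggregates()["nmse"]["mean"] > 0

    def test_aggregates_recomputable(self, rng):
        report = evaluate_reconstruction(_toy_pairs(rng=rng),
                                         lambda img, ys, yt: img)
        agg = report.aggregates()
        assert agg["ssim"]["mean"] == pytest.approx(report.per_pair["ssim"].mean())
        assert agg["ssim"]["sd"] == pytest.approx(report.per_pair["ssim"].std(ddof=1))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate_reconstruction([], lambda img, ys, yt: img)


class TestEvaluateConditioning:
    def test_oracle_ac_perfect(self):
        pairs = _toy_pairs()

        def oracle_ac(image):
            # reads the (constant) target label of the toy pairs
            return np.array([40.0 / 50, 3000.0 / 5000, 10.0])

        report = evaluate_conditioning(pairs, lambda img, ys, yt: img, oracle_ac)
        assert report.conditioning["te_mae_ms"] == pytest.approx(0.0, abs=1e-9)
        assert report.conditioning["fs_accuracy_pct"] == 100.0

    def test_constant_ac_mae_by_hand(self):
        pairs = _toy_pairs()
        report = evaluate_conditioning(
            pairs, lambda img, ys, yt: img,
            lambda image: np.array([0.5, 0.5, -1.0]))
        # |0.5*50 - 40| = 15 ms TE, |0.5*5000 - 3000| = 500 ms TR, FS wrong
        assert report.conditioning["te_mae_ms"] == pytest.approx(15.0)
        assert report.conditioning["tr_mae_ms"] == pytest.approx(500.0)
        assert report.conditioning["fs_accuracy_pct"] == 0.0

    def test_untrained_ac_rejected(self):
        class Untrained:
            trained = False

            def predict(self, image):
                return np.zeros(3)

        with pytest.raises(RuntimeError):
            evaluate_conditioning(_toy_pairs(), lambda img, ys, yt: img,
                                  Untrained())


def test_compare_models_t_test(rng):
    a = rng.normal(0.6, 0.05, size=30)
    b = rng.normal(0.7, 0.05, size=30)
    result = compare_models(a, b)
    assert result.pvalue < 0.05
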