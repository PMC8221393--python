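"""U-net architecture contract, gradient correctness, training behavior,
and the training-mask preparation utilities."""

import numpy as np
import pytest

from cardiomorph import nn, phantom, unet
from cardiomorph.mechanics import dice


class TestSpecValidation:
    def test_input_must_be_power_of_two(self):
        with pytest.raises(ValueError, match="power of two"):
            unet.UNetSpec(input_size=100)

    def test_input_must_cover_depth(self):
        with pytest.raises(ValueError, match="divisible"):
            unet.UNetSpec(input_size=8, depth=4)

    def test_full_scale_bottleneck_is_32(self):
        # 512 / 2^4 = 32 at the bottom of the contracting path
        model = unet.build_unet(unet.UNetSpec(), seed=0)
        ledger = model.level_ledger()
        assert ledger[-1] == {"level": 4, "channels": 1024, "spatial": 32}

    @pytest.mark.parametrize(
        "spec",
        [unet.UNetSpec(), unet.UNetSpec.reduced()],
        ids=["full", "reduced"],
    )
    def test_channel_size_ledger(self, spec):
        """Level j has base·2^j channels at spatial size A/2^j, and the built
        weights actually have those channel counts."""
        model = unet.build_unet(spec, seed=0)
        for j, row in enumerate(model.level_ledger(), start=1):
            assert row["channels"] == spec.base_features * 2**j
            assert row["spatial"] == spec.input_size // 2**j
        # encoder conv weights: block j outputs base·2^j channels (j from 0)
        for j, block in enumerate(model.enc):
            assert block.layers[0].W.shape[0] == spec.base_features * 2**j
        assert model.bottleneck.layers[0].W.shape[0] == spec.base_features * 2**spec.depth


class TestGradients:
    def test_backprop_matches_numerical_directional_derivative(self):
        """Exact float64 check of the full network's backward pass."""
        spec = unet.UNetSpec(input_size=16, depth=2, base_features=3)
        model = unet.build_unet(spec, seed=0)
        model.cast(np.float64)
        rng = np.random.default_rng(1)
        x = rng.random((2, 16, 16, 1))
        y = (rng.random((2, 16, 16, 1)) > 0.5).astype(np.float64)
        _, g = nn.bce_with_logits(model.forward(x), y)
        model.backward(g)
        params = model.params()
        dirs = [rng.normal(size=p.shape) for p, _ in params]
        analytic = sum(float(np.sum(gr * d)) for (p, gr), d in zip(params, dirs))
        eps = 1e-6
        for (p, _), d in zip(params, dirs):
            p += eps * d
        lp, _ = nn.bce_with_logits(model.forward(x), y)
        for (p, _), d in zip(params, dirs):
            p -= 2 * eps * d
        lm, _ = nn.bce_with_logits(model.forward(x), y)
        numeric = (lp - lm) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=1e-5)

    def test_bce_loss_and_gradient_closed_form(self):
        z = np.array([[0.0, 2.0], [-2.0, 0.5]], dtype=np.float64)
        y = np.array([[1.0, 0.0], [1.0, 1.0]], dtype=np.float64)
        loss, grad = nn.bce_with_logits(z, y)
        p = 1 / (1 + np.exp(-z))
        expect = float(np.mean(-(y * np.log(p) + (1 - y) * np.log(1 - p))))
        assert loss == pytest.approx(expect, rel=1e-12)
        assert np.allclose(grad, (p - y) / 4)


class TestTraining:
    def test_zero_epochs_returns_unchanged_model(self):
        model = unet.build_unet(unet.UNetSpec(input_size=32, depth=2, base_features=2))
        before = [p.copy() for p, _ in model.params()]
        rng = np.random.default_rng(0)
        imgs = rng.random((4, 32, 32)).astype(np.float32)
        msks = (rng.random((4, 32, 32)) > 0.5).astype(np.uint8)
        model, hist = unet.train(model, imgs, msks, unet.TrainSpec(epochs=0))
        assert hist == []
        for b, (p, _) in zip(before, model.params()):
            assert np.array_equal(b, p)

    def test_mismatched_counts_rejected(self):
        model = unet.build_unet(unet.UNetSpec(input_size=32, depth=2, base_features=2))
        imgs = np.zeros((4, 32, 32), dtype=np.float32)
        msks = np.zeros((3, 32, 32), dtype=np.uint8)
        with pytest.raises(ValueError, match="images but"):
            unet.train(model, imgs, msks, unet.TrainSpec(epochs=1))

    def test_overfit_contract_on_five_slices(self):
        """A small run on 5 phantom slices memorizes them (train Dice ≥ 0.95).

        Five slices give one optimizer step per epoch, so memorization takes
        ~200 epochs of the default Adam settings."""
        imgs, msks = phantom.training_slices(range(5))
        model = unet.build_unet(unet.UNetSpec.reduced(), seed=0)
        spec = unet.TrainSpec(epochs=200, batch_size=8, learning_rate=1e-3, seed=0)
        model, hist = unet.train(model, imgs, msks, spec)
        assert hist[-1] < hist[0]
        scores = [
            dice(unet.predict(model, imgs[i]) >= 0.5, msks[i] > 0) for i in range(5)
        ]
        assert np.mean(scores) >= 0.95

    def test_loss_decreases_and_heldout_dice_high(self, reference_run):
        """After the standard training run, held-out phantom slices segment
        at high Dice (the 0.95-regime contract is checked in acceptance)."""
        _model, scores, history = reference_run
        assert history[-1] < history[0]
        assert np.mean(scores) >= 0.9

    def test_predict_deterministic_and_bounded(self, small_model):
        model = small_model[0]
        img, _ = phantom.training_slice(3)
        p1 = unet.predict(model, img)
        p2 = unet.predict(model, img)
        assert np.array_equal(p1, p2)
        assert p1.min() >= 0.0 and p1.max() <= 1.0

    def test_save_load_round_trip(self, small_model, tmp_path):
        model = small_model[0]
        unet.save_model(model, tmp_path / "m")
        loaded = unet.load_model(tmp_path / "m")
        img, _ = phantom.training_slice(5)
        assert np.array_equal(unet.predict(model, img), unet.predict(loaded, img))


class TestThreshold:
    def test_uniform_high_probability_gives_full_mask(self):
        assert unet.threshold(np.full((4, 4), 0.7), 0.5).all()

    def test_threshold_partitions_the_plane(self):
        rng = np.random.default_rng(0)
        p = rng.random((16, 16))
        m = unet.threshold(p, 0.5)
        assert (m | (p < 0.5)).all()


class TestPreprocessMask:
    def test_constant_mask_unchanged(self):
        m = np.ones((32, 32), dtype=np.uint8)
        assert unet.preprocess_mask(m, 2.0).all()

    def test_isolated_pixel_removed_at_2um_pitch(self):
        m = np.zeros((33, 33), dtype=np.uint8)
        m[16, 16] = 1
        assert not unet.preprocess_mask(m, 2.0).any()

    def test_half_plane_boundary_moves_less_than_one_pixel(self):
        m = np.zeros((64, 64), dtype=np.uint8)
        m[:, :32] = 1
        out = unet.preprocess_mask(m, 2.0)
        assert out[:, :31].all() and not out[:, 33:].any()

    def test_nonbinary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            unet.preprocess_mask(np.full((8, 8), 3), 2.0)

    def test_nonpositive_pitch_rejected(self):
        with pytest.raises(ValueError):
            unet.preprocess_mask(np.zeros((8, 8), dtype=np.uint8), 0.0)


def disk(r, size=64):
    yy, xx = np.mgrid[:size, :size] - size // 2
    return (yy**2 + xx**2 <= r**2).astype(np.uint8)


class TestInterpolateContours:
    def test_identical_flanks_give_identical_intermediates(self):
        m = disk(10)
        out = unet.interpolate_contours([m, m], [0, 4])
        assert out.shape[0] == 5
        for z in range(5):
            assert np.array_equal(out[z], m.astype(bool))

    def test_midpoint_between_disks_has_intermediate_radius(self):
        out = unet.interpolate_contours([disk(10), disk(20)], [0, 10])
        mid = out[5]
        r_mid = np.sqrt(mid.sum() / np.pi)
        assert abs(r_mid - 15.0) <= 1.0

    def test_empty_flanks_give_empty_intermediates(self):
        e = np.zeros((16, 16), dtype=np.uint8)
        out = unet.interpolate_contours([e, e], [0, 3])
        assert not out.any()

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            unet.interpolate_contours([disk(5)], [0])


class TestSplitTrainVal:
    def test_80_20_split_of_ten(self):
        tr, va = unet.split_train_val(list(range(10)), 0.8, seed=0)
        assert len(tr) == 8 and len(va) == 2
        assert sorted(tr + va) == list(range(10))

    def test_same_seed_reproduces_split(self):
        a = unet.split_train_val(list(range(20)), 0.8, seed=3)
        b = unet.split_train_val(list(range(20)), 0.8, seed=3)
        assert a == b

    def test_validation_never_empty(self):
        tr, va = unet.split_train_val(list(range(10)), 0.999, seed=0)
        assert len(tr) == 9 and len(va) == 1

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            unet.split_train_val([1], 0.8)
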