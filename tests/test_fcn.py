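"""Slice pipeline, balanced loss, and fusion-network mechanics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvseg.core import LabelMask, Volume
from lvseg.fcn import (
    NetConfig,
    SliceStack,
    TrainConfig,
    build_network,
    predict_stack,
    restack,
    slice_volume,
    to_three_channel,
    train,
    weighted_ce_loss,
)
from lvseg.fcn.data import apply_transform, augment
from lvseg.fcn.nn import Conv2d, ResidualBlock


class TestSliceVolume:
    def test_slice_count_equals_z_extent(self, noiseless):
        _, vol, mask, _ = noiseless
        stack = slice_volume(vol, mask)
        assert len(stack) == vol.shape[2]
        assert (stack.z_index == np.arange(vol.shape[2])).all()

    def test_restack_round_trips_exactly(self, noiseless):
        _, vol, mask, _ = noiseless
        vol2, mask2 = restack(slice_volume(vol, mask))
        assert np.array_equal(vol2.data, vol.data)
        assert np.array_equal(mask2.data, mask.data)

    def test_per_slice_foreground_matches_plane_counts(self, noiseless):
        _, vol, mask, _ = noiseless
        stack = slice_volume(vol, mask)
        for z in range(vol.shape[2]):
            assert stack.masks[z].sum() == mask.data[:, :, z].sum()

    def test_shape_mismatch_rejected(self):
        vol = Volume(np.zeros((8, 8, 4)))
        bad = LabelMask(np.zeros((8, 8, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            slice_volume(vol, bad)


class TestToThreeChannel:
    def test_channels_identical(self, rng):
        img = rng.random((32, 24))
        out = to_three_channel(img)
        assert out.shape == (3, 32, 24)
        assert np.array_equal(out[0], img)
        assert np.array_equal(out[1], out[0]) and np.array_equal(out[2], out[0])

    def test_zero_image(self):
        out = to_three_channel(np.zeros((8, 8)))
        assert out.shape == (3, 8, 8) and not out.any()

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            to_three_channel(np.zeros((3, 8, 8)))


class TestAugment:
    def _stack(self, rng, n=4):
        imgs = rng.random((n, 32, 32))
        masks = np.zeros((n, 32, 32), dtype=np.uint8)
        masks[:, 10:20, 12:22] = 1
        return SliceStack(imgs, masks, np.arange(n))

    def test_zero_augments_identity(self, rng):
        stack = self._stack(rng)
        assert augment(stack, 0) is stack

    def test_output_size_multiplied(self, rng):
        stack = self._stack(rng, n=5)
        out = augment(stack, n_augments=3, seed=0)
        assert len(out) == 5 * 4

    def test_exact_90_degree_rotation_preserves_foreground_count(self, rng):
        mask = (rng.random((32, 32)) > 0.6).astype(float)
        rotated = apply_transform(mask, 90.0, 1.0) > 0.5
        assert rotated.sum() == mask.sum()
        assert np.array_equal(rotated, np.rot90(mask.astype(bool), k=-1))

    def test_fixed_seed_reproducible(self, rng):
        stack = self._stack(rng)
        a = augment(stack, 2, seed=42)
        b = augment(stack, 2, seed=42)
        assert np.array_equal(a.images, b.images)
        assert np.array_equal(a.masks, b.masks)

    def test_masks_stay_binary(self, rng):
        out = augment(self._stack(rng), 2, rotation_range=45, scale_range=0.2, seed=1)
        assert set(np.unique(out.masks)) <= {0, 1}


class TestWeightedCELoss:
    def test_balanced_mask_gives_half_weight(self):
        truth = np.zeros((4, 4))
        truth[:2] = 1
        probs = np.full((4, 4), 0.5)
        terms = weighted_ce_loss(probs, truth)
        assert terms.a == 0.5
        assert terms.Y_plus == terms.Y_minus == 8

    def test_perfect_prediction_loss_vanishes(self):
        truth = (np.arange(16).reshape(4, 4) % 3 == 0).astype(float)
        probs = truth.astype(np.float64)
        terms = weighted_ce_loss(probs, truth)
        assert 0.0 <= terms.loss < 1e-9

    def test_hand_computed_example(self):
        # 2x2 truth with one foreground pixel: a = 3/4;
        # P(y=1)=0.8 there, P(y=0)=0.6 at the three background pixels
        truth = np.array([[1.0, 0.0], [0.0, 0.0]])
        p1 = np.array([[0.8, 0.4], [0.4, 0.4]])
        terms = weighted_ce_loss(p1, truth)
        expected = -0.75 * np.log(0.8) - 0.25 * (3 * np.log(0.6))
        assert terms.a == 0.75
        assert terms.loss == pytest.approx(expected, abs=1e-12)
        assert terms.loss == pytest.approx(0.5504, abs=5e-4)

    def test_zero_probability_clamped_never_nan(self):
        truth = np.array([[1.0, 0.0], [0.0, 0.0]])
        p1 = np.zeros((2, 2))
        terms = weighted_ce_loss(p1, truth)
        assert np.isfinite(terms.loss)

    @given(st.integers(0, 2**32 - 1))
    @settings(deadline=None, max_examples=25)
    def test_matches_per_pixel_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        truth = (rng.random((16, 16)) > 0.7).astype(float)
        p1 = np.clip(rng.random((16, 16)), 1e-6, 1 - 1e-6)
        terms = weighted_ce_loss(p1, truth)
        # brute force per-pixel summation
        yp = truth.sum()
        a = (truth.size - yp) / truth.size
        acc = 0.0
        for i in range(16):
            for j in range(16):
                if truth[i, j]:
                    acc -= a * np.log(p1[i, j])
                else:
                    acc -= (1 - a) * np.log(1 - p1[i, j])
        assert terms.loss == pytest.approx(acc, rel=1e-10)

    def test_permutation_invariance_within_class_groups(self, rng):
        truth = (rng.random((8, 8)) > 0.5).astype(float)
        p1 = np.clip(rng.random((8, 8)), 0.01, 0.99)
        base = weighted_ce_loss(p1, truth).loss
        # shuffle probabilities within the foreground and within the background
        p2 = p1.copy()
        for cls in (0, 1):
            sel = truth == cls
            vals = p2[sel]
            p2[sel] = rng.permutation(vals)
        assert weighted_ce_loss(p2, truth).loss == pytest.approx(base, rel=1e-12)

    def test_half_weight_equals_half_unweighted_ce(self, rng):
        truth = np.zeros((6, 6))
        truth[:3] = 1  # exactly balanced -> a = 1/2
        p1 = np.clip(rng.random((6, 6)), 0.01, 0.99)
        loss = weighted_ce_loss(p1, truth).loss
        unweighted = -(
            np.log(p1[truth == 1]).sum() + np.log(1 - p1[truth == 0]).sum()
        )
        assert loss == pytest.approx(0.5 * unweighted, rel=1e-12)


class TestNetwork:
    def test_forward_shape_and_softmax_normalization(self, rng):
        net = build_network(NetConfig(base_width=2), seed=0)
        probs = net.predict_probs(rng.random((1, 3, 64, 64)))
        assert probs.shape == (1, 2, 64, 64)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_non_divisible_input_padded_and_cropped(self, rng):
        net = build_network(NetConfig(base_width=2), seed=0)
        probs = net.predict_probs(rng.random((1, 3, 50, 37)))
        assert probs.shape == (1, 2, 50, 37)

    def test_stream_parameter_count_bookkeeping(self):
        full = build_network(NetConfig(base_width=4, skip_streams=(1, 2, 3, 4)), seed=0)
        reduced = build_network(NetConfig(base_width=4, skip_streams=(2, 3, 4)), seed=0)
        diff = full.parameter_count() - reduced.parameter_count()
        # the P1 stream: residual block (4 conv + 4 BN), 1x1 score conv, x2 upsampler
        w = full.cfg.stage_width(1)
        res_params = 4 * (w * w * 9 + w) + 4 * (2 * w)
        score_params = w * 2 + 2
        up_params = 2 * 2 * 2 * 2 + 2
        assert diff == res_params + score_params + up_params

    def test_residual_block_with_zero_weights_is_identity(self, rng):
        block = ResidualBlock(4, n_layers=4, rng=np.random.default_rng(0))
        for p in block.params():
            if p.name.endswith(".W") or p.name.endswith(".beta"):
                p.value[...] = 0.0
        block.set_training(False)
        x = rng.random((2, 4, 8, 8))
        assert np.allclose(block.forward(x), x)

    def test_baseline_deep_streams_always_present(self):
        cfg = NetConfig(base_width=2, skip_streams=(1,))
        assert set(cfg.skip_streams) >= {3, 4}
        with pytest.raises(ValueError):
            NetConfig(skip_streams=())

    def test_weight_interchange_round_trip(self, tmp_path, rng):
        net = build_network(NetConfig(base_width=2), seed=0)
        x = rng.random((1, 3, 32, 32))
        net.set_training(False)
        ref = net.predict_probs(x)
        net.save_npz(tmp_path / "w.npz")
        other = build_network(NetConfig(base_width=2), seed=99)
        other.load_npz(tmp_path / "w.npz")
        other.set_training(False)
        assert np.allclose(other.predict_probs(x), ref)


class TestTraining:
    def _toy_stack(self, rng, n=24, size=32):
        imgs = np.full((n, size, size), 0.7)
        masks = np.zeros((n, size, size), dtype=np.uint8)
        for i in range(n):
            cx, cy = rng.integers(10, size - 10, 2)
            r = rng.integers(4, 8)
            x, y = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
            d = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
            masks[i][d] = 1
            imgs[i][d] = 0.15
        imgs += rng.normal(0, 0.03, imgs.shape)
        return SliceStack(imgs, masks, np.arange(n))

    def test_stage1_freezes_backbone_bit_identical(self, rng):
        # during stage 1 only head parameters may move; the backbone is frozen
        from lvseg.fcn.data import to_three_channel as t3
        from lvseg.fcn.nn import SGD
        from lvseg.fcn.train import _loss_and_grad_batch

        stack = self._toy_stack(rng)
        net = build_network(NetConfig(base_width=2), seed=0)
        backbone_before = {p.name: p.value.copy() for p in net.backbone_parameters()}
        head_before = {p.name: p.value.copy() for p in net.head_parameters()}
        opt = SGD(net.parameters(), 0.05, 0.9)
        net.set_training(True)
        net.freeze_backbone(True)
        for _ in range(3):
            x = np.stack([t3(im) for im in stack.images[:4]])
            probs = net.predict_probs(x)
            _, d = _loss_and_grad_batch(probs, stack.masks[:4])
            opt.zero_grad()
            net.backward(d)
            opt.step()
        for p in net.backbone_parameters():
            assert np.array_equal(p.value, backbone_before[p.name])
        assert any(
            not np.array_equal(p.value, head_before[p.name])
            for p in net.head_parameters()
        )

    def test_equal_seeds_identical_loss_histories(self, rng):
        stack = self._toy_stack(rng)
        cfg = TrainConfig(lr0=0.05, momentum=0.9, batch_size=4, max_iter=10,
                          stage1_iter=3, decay_every=5, seed=7)
        l1 = train(build_network(NetConfig(base_width=2), seed=3), stack, cfg).losses
        l2 = train(build_network(NetConfig(base_width=2), seed=3), stack, cfg).losses
        assert l1 == l2

    def test_lr_schedule_steps_linearly(self):
        cfg = TrainConfig(lr0=1e-4, max_iter=10000, stage1_iter=1000, decay_every=1000)
        assert cfg.lr_at(0) == 1e-4
        assert cfg.lr_at(999) == 1e-4
        assert cfg.lr_at(1000) == pytest.approx(1e-4 * 0.9)
        assert cfg.lr_at(9999) == pytest.approx(1e-4 * 0.1)

    def test_prediction_restacks_to_source_geometry(self, noiseless):
        _, vol, mask, _ = noiseless
        stack = slice_volume(vol, mask)
        net = build_network(NetConfig(base_width=2), seed=0)
        pred = predict_stack(net, stack)
        vol2, predmask = restack(pred)
        assert predmask.shape == mask.shape
        assert predmask.spacing == mask.spacing

    def test_inference_deterministic_and_intensity_independent_argmax(self):
        # eval-mode inference is a pure function of the input
        net = build_network(NetConfig(base_width=2), seed=0)
        net.set_training(False)
        x = np.full((1, 3, 32, 32), 0.4)
        p1 = net.predict_probs(x)
        p2 = net.predict_probs(x.copy())
        assert np.array_equal(p1, p2)

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(stage1_iter=0)
        with pytest.raises(ValueError):
            TrainConfig(stage1_iter=100, max_iter=100)
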