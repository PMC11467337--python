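"""The NumPy 3D CNN: architecture contracts, gradients, loss arithmetic,
augmentation and inference conventions."""

import math

import numpy as np
import pytest

from tomoblast.nn import (ArchConfig, AugmentParams, TINY_ARCH, TrainConfig,
                          augment_volume, build_network, class_weights,
                          weighted_cross_entropy)
from tomoblast.nn.layers import Conv3d
from tomoblast.nn.network import TomoNet
from tomoblast.nn.train import (cosine_lr, load_checkpoint, predict,
                                predict_batch, save_checkpoint, train)


def param_count_oracle(arch: ArchConfig) -> int:
    """Independent layer-walk: channel arithmetic re-derived from scratch."""
    def conv(ci, co, k):
        return ci * co * k ** 3 + co

    def bottleneck(ci, co, red):
        cm = max(1, co // red)
        return (2 * ci                      # shared pre-activation norm
                + conv(ci, co, 1)           # skip path
                + conv(ci, cm, 1) + 2 * cm
                + conv(cm, cm, 3) + 2 * cm
                + conv(cm, co, 1))

    s, w, r, L = arch.stages, arch.base_width, arch.reduction, arch.latent_dim
    total = conv(1, w, 3)
    taps = []
    c = w
    for _ in range(s):
        taps.append(c)
        total += bottleneck(c, 2 * c, r)
        c *= 2
    for i in range(s):
        ch = max(1, c // 2)
        total += bottleneck(c, ch, r)
        c = ch + taps[s - 1 - i]
    for _ in range(s):
        total += bottleneck(c, 2 * c, r)
        c *= 2
    total += c * L + L                      # latent projection
    total += L * 2 + 2                      # output layer
    return total


class TestArchitecture:
    def test_single_conv_parameter_count(self):
        layer = Conv3d(4, 8, 3, np.random.default_rng(0))
        assert layer.n_params == 872  # 4*8*27 + 8

    @pytest.mark.parametrize("arch", [
        TINY_ARCH,
        ArchConfig(input_shape=(8, 16, 16), stages=2, base_width=6, reduction=3,
                   latent_dim=17),
        ArchConfig(input_shape=(16, 16, 16), stages=1, base_width=3, reduction=2,
                   latent_dim=9),
    ])
    def test_parameter_count_matches_layer_walk(self, arch):
        _, n = build_network(arch, rng=0)
        assert n == param_count_oracle(arch)

    def test_forward_shape_contract(self):
        model, _ = build_network(TINY_ARCH, rng=0)
        x = np.zeros((3,) + TINY_ARCH.input_shape, np.float32)
        out = model.forward(x, training=False)
        assert out.shape == (3, 2)
        assert model.latent.shape == (3, TINY_ARCH.latent_dim)

    def test_indivisible_shape_rejected_before_allocation(self):
        bad = ArchConfig(input_shape=(10, 32, 32), stages=2, base_width=4)
        with pytest.raises(ValueError, match="divisible"):
            build_network(bad)

    def test_bottleneck_gradients_match_finite_differences(self):
        """Strict directional FD check on a pool-free residual block (the
        smooth part of the graph; max-pool argmax kinks are excluded)."""
        from tomoblast.nn.network import Bottleneck

        blk = Bottleneck(3, 4, 2, 0.1, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 3, 5, 5, 5)).astype(np.float32)
        target = rng.standard_normal((2, 4, 5, 5, 5)).astype(np.float32)

        # L = sum(diff^2) / (2N) with dL/dout = diff/N
        for l in blk.sublayers:
            l.zero_grad()
        out = blk.forward(x, training=True)
        diff = out - target
        blk.backward(diff / diff.size)
        params = [(l, k) for l in blk.sublayers for k in l.params]
        g = np.concatenate([l.grads[k].ravel() for l, k in params]).astype(np.float64)
        gn = np.linalg.norm(g)
        direction = g / gn
        orig = [l.params[k].copy() for l, k in params]

        def shift(eps):
            i = 0
            for (l, k), o in zip(params, orig):
                l.params[k] = (o.astype(np.float64)
                               + eps * direction[i:i + o.size].reshape(o.shape)
                               ).astype(np.float32)
                i += o.size

        def loss():
            d = blk.forward(x, training=False) - target
            return float(0.5 * (d.astype(np.float64) ** 2).sum() / d.size)

        eps = 1e-3
        shift(+eps)
        l1 = loss()
        shift(-eps)
        l2 = loss()
        numeric = (l1 - l2) / (2 * eps)
        assert abs(numeric - gn) / gn < 1e-2

    def test_full_network_gradients_approximate_finite_differences(self):
        """Whole-graph directional FD check; loose tolerance because finite
        perturbations can flip max-pool argmax selections."""
        arch = ArchConfig(input_shape=(4, 4, 4), stages=1, base_width=2,
                          reduction=2, latent_dim=3)
        model = TomoNet(arch, rng=1)
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 4, 4, 4)).astype(np.float32)
        y = np.array([0, 1])
        w = np.array([1.3, 0.7])
        model.zero_grad()
        _, dout = weighted_cross_entropy(model.forward(x, training=True), y, w)
        model.backward(dout)
        params = [(l, k) for l in model.layers for k in l.params]
        g = np.concatenate([l.grads[k].ravel() for l, k in params]).astype(np.float64)
        gn = np.linalg.norm(g)
        direction = g / gn
        orig = [l.params[k].copy() for l, k in params]

        def shift(eps):
            i = 0
            for (l, k), o in zip(params, orig):
                l.params[k] = (o.astype(np.float64)
                               + eps * direction[i:i + o.size].reshape(o.shape)
                               ).astype(np.float32)
                i += o.size

        eps = 1e-3
        shift(+eps)
        l1, _ = weighted_cross_entropy(model.forward(x, training=False), y, w)
        shift(-eps)
        l2, _ = weighted_cross_entropy(model.forward(x, training=False), y, w)
        numeric = (l1 - l2) / (2 * eps)
        assert abs(numeric - gn) / gn < 0.10


class TestLoss:
    def test_weighted_cross_entropy_matches_hand_arithmetic(self):
        logits = np.array([[0.2, -0.3], [1.0, 0.5]])
        labels = np.array([0, 1])
        weights = np.array([2.0, 1.0])
        loss, _ = weighted_cross_entropy(logits, labels, weights)
        # hand-computed: softmax NLLs weighted 2:1, normalized by sum of weights
        p0 = math.exp(0.2) / (math.exp(0.2) + math.exp(-0.3))
        p1 = math.exp(0.5) / (math.exp(1.0) + math.exp(0.5))
        expected = (2.0 * -math.log(p0) + 1.0 * -math.log(p1)) / 3.0
        assert loss == pytest.approx(expected, abs=1e-6)

    def test_balanced_weights_reduce_to_plain_cross_entropy(self):
        labels = np.array([0, 1, 0, 1])
        w = class_weights(labels)
        assert np.allclose(w, [1.0, 1.0])
        logits = np.random.default_rng(0).normal(size=(4, 2))
        weighted, _ = weighted_cross_entropy(logits, labels, w)
        plain = 0.0
        for z, y in zip(logits, labels):
            e = np.exp(z - z.max())
            plain += -math.log(e[y] / e.sum())
        assert weighted == pytest.approx(plain / 4, abs=1e-9)

    def test_inverse_class_weights_balance_contributions(self):
        labels = np.array([0, 0, 0, 1])
        w = class_weights(labels)
        # per-class weight x count is equal: errors penalized evenly
        assert w[0] * 3 == pytest.approx(w[1] * 1)

    def test_single_class_weights_error(self):
        with pytest.raises(ValueError):
            class_weights(np.array([1, 1, 1]))

    def test_cosine_schedule_restarts(self):
        assert cosine_lr(0, 1.0, 32) == pytest.approx(1.0)
        assert cosine_lr(16, 1.0, 32) == pytest.approx(0.5)
        assert cosine_lr(32, 1.0, 32) == pytest.approx(1.0)  # warm restart


class _StubRng:
    """Deterministic stand-in driving specific augmentations."""

    def __init__(self, angle=0.0, shifts=(0, 0, 0), flip=False):
        self.angle, self.shifts, self.flip = angle, list(shifts), flip

    def uniform(self, lo, hi):
        return self.angle

    def integers(self, lo, hi):
        return self.shifts.pop(0)

    def random(self):
        return 0.0 if self.flip else 1.0

    def normal(self, loc, scale, size=None):
        return np.zeros(size)


class TestAugment:
    def test_identity_parameters(self):
        vol = np.random.default_rng(0).normal(size=(8, 12, 12)).astype(np.float32)
        params = AugmentParams(noise_sd=0.0, max_translation=(0, 0, 0),
                               flip_axes=(), rotation_deg=0.0)
        out = augment_volume(vol, params, np.random.default_rng(1))
        assert np.array_equal(out, vol)

    def test_flip_twice_is_identity(self):
        vol = np.random.default_rng(0).normal(size=(8, 12, 12)).astype(np.float32)
        params = AugmentParams(noise_sd=0.0, max_translation=(0, 0, 0),
                               flip_axes=(1, 2), rotation_deg=0.0)
        once = augment_volume(vol, params, _StubRng(flip=True))
        twice = augment_volume(once, params, _StubRng(flip=True))
        assert np.array_equal(twice, vol)

    def test_quarter_turn_transposes_a_bar(self):
        vol = np.zeros((4, 21, 21), np.float32)
        vol[:, 10, 3:18] = 1.0  # bar along x
        params = AugmentParams(noise_sd=0.0, max_translation=(0, 0, 0),
                               flip_axes=(), rotation_deg=90.0)
        out = augment_volume(vol, params, _StubRng(angle=90.0))
        assert (out > 0.5)[0, 3:18, 10].all()  # bar now along y
        n_in, n_out = (vol > 0.5).sum(), (out > 0.5).sum()
        assert abs(n_out - n_in) / n_in < 0.01

    def test_translation_pads_with_fill(self):
        vol = np.ones((4, 6, 6), np.float32)
        params = AugmentParams(noise_sd=0.0, max_translation=(0, 2, 0),
                               flip_axes=(), rotation_deg=0.0)
        out = augment_volume(vol, params, _StubRng(shifts=[2, 0]), fill=-1.0)
        assert (out[:, :2, :] == -1.0).all()

    def test_oversized_translation_clipped_with_warning(self):
        vol = np.ones((4, 6, 6), np.float32)
        params = AugmentParams(noise_sd=0.0, max_translation=(0, 99, 0),
                               flip_axes=(), rotation_deg=0.0)
        with pytest.warns(UserWarning, match="clipping"):
            augment_volume(vol, params, np.random.default_rng(0))


class _TwoScoreModel:
    """Inference stub with fixed outputs, for the prediction conventions."""

    def __init__(self, scores):
        self.scores = np.asarray(scores, np.float32)
        self.arch = TINY_ARCH

    def forward(self, x, training=False):
        self.latent = np.zeros((len(x), 4), np.float32)
        return self.scores[: len(x)]


class TestPredict:
    def test_argmax_and_tie_convention(self):
        model = _TwoScoreModel([[0.3, 0.7], [0.7, 0.3], [0.5, 0.5]])
        recs = predict_batch(model, np.zeros((3, 2, 2, 2), np.float32))
        assert [r.predicted_label for r in recs] == ["MUT", "WT", "WT"]

    def test_repeat_prediction_identical(self):
        model, _ = build_network(TINY_ARCH, rng=3)
        vol = np.random.default_rng(0).normal(size=TINY_ARCH.input_shape) \
            .astype(np.float32)
        a = predict(model, vol, "img")
        b = predict(model, vol, "img")
        assert a.out_wt == b.out_wt and a.out_mut == b.out_mut
        assert np.array_equal(a.latent, b.latent)

    def test_shape_mismatch_rejected(self):
        model, _ = build_network(TINY_ARCH, rng=3)
        with pytest.raises(ValueError, match="shape"):
            predict(model, np.zeros((8, 8, 8), np.float32))


def _tiny_training_data(n=24):
    rng = np.random.default_rng(5)
    x = rng.normal(0, 0.1, size=(n, 8, 16, 16)).astype(np.float32)
    y = np.arange(n) % 2
    x[y == 1, 2:6, 4:12, 4:12] += 0.5
    split = np.array(["optimization"] * (n - 8) + ["generalization"] * 8)
    return x, y, split


class TestTraining:
    ARCH = ArchConfig(input_shape=(8, 16, 16), stages=1, base_width=2,
                      reduction=2, latent_dim=4)

    def test_history_and_checkpoint_selection_reproducible(self):
        x, y, split = _tiny_training_data()
        cfg = TrainConfig(epochs=3, seed=9, batch_size=8,
                          augment=AugmentParams(noise_sd=0.01,
                                                max_translation=(1, 1, 1),
                                                rotation_deg=20))
        m1, h1 = train(x, y, split, self.ARCH, cfg)
        m2, h2 = train(x, y, split, self.ARCH, cfg)
        assert h1.equals(h2)
        assert h1.selected.sum() == 1
        s1, s2 = m1.state_dict(), m2.state_dict()
        assert all(np.array_equal(s1[k], s2[k]) for k in s1)

    def test_single_class_training_rejected(self):
        x, y, split = _tiny_training_data()
        with pytest.raises(ValueError, match="single class"):
            train(x, np.zeros_like(y), split, self.ARCH, TrainConfig(epochs=1, seed=0))

    def test_checkpoint_round_trip(self, tmp_path):
        x, y, split = _tiny_training_data()
        cfg = TrainConfig(epochs=1, seed=2, batch_size=8)
        model, _ = train(x, y, split, self.ARCH, cfg)
        path = save_checkpoint(tmp_path / "ckpt.npz", model, cfg)
        loaded, cfg2 = load_checkpoint(path)
        assert cfg2 == cfg
        a = model.forward(x[:4], training=False)
        b = loaded.forward(x[:4], training=False)
        assert np.allclose(a, b, atol=1e-6)
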