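"""Dual-Net construction, forward contracts, and training behavior."""

import numpy as np
import pytest

from dbtnet import nn
from dbtnet.backbones import REGISTRY, build_backbone, get_spec
from dbtnet.evaluate import auc
from dbtnet.model import (DualNet, DualNetConfig, build_dual_net,
                          classify_variant)
from dbtnet.train import Trainer


class TestRegistry:
    def test_published_taxonomy(self):
        shallow = {"mobilenetv2", "alexnet", "resnet18"}
        deep = {"resnet50", "resnext50", "densenet121", "densenet201"}
        for name in shallow:
            assert get_spec(name).category == "shallow"
        for name in deep:
            assert get_spec(name).category == "deep"

    def test_unknown_backbone_lists_registry(self):
        with pytest.raises(KeyError, match="available"):
            get_spec("vgg16")

    @pytest.mark.parametrize("name", sorted(REGISTRY))
    def test_backbones_construct_and_forward(self, name):
        net = build_backbone(name, np.random.default_rng(0))
        net.eval()
        y = net(np.random.default_rng(1).standard_normal((1, 3, 64, 64)))
        assert y.shape[1] == get_spec(name).feature_channels
        assert np.all(np.isfinite(y))


class TestConstruction:
    def test_dimension_bookkeeping(self, tiny_dualnet):
        x = np.random.default_rng(0).random((2, 3, 64, 64))
        pair, pred = tiny_dualnet.forward(x)
        d_s = get_spec("tinycnn-shallow").feature_channels
        d_d = get_spec("tinycnn-deep").feature_channels
        assert pair.v_s.shape == (2, d_s)
        assert pair.v_d.shape == (2, d_d)
        assert pair.z.shape == (2, d_s + d_d)
        assert pair.fhat_s.shape == pair.fhat_d.shape == (2, 8)

    def test_best_published_pair_constructible(self):
        cfg = DualNetConfig(shallow="alexnet", deep="resnet50", proj_dim=16,
                            seed=0)
        model = build_dual_net(cfg)
        assert model.d_s == 256 and model.d_d == 2048

    def test_category_slots_enforced(self):
        with pytest.raises(ValueError, match="not a shallow"):
            DualNetConfig(shallow="resnet50", deep="densenet121")
        with pytest.raises(ValueError, match="not a deep"):
            DualNetConfig(shallow="alexnet", deep="alexnet")

    def test_wrong_channel_count_rejected(self, tiny_dualnet):
        with pytest.raises(ValueError, match=r"\(N, 3, H, W\)"):
            tiny_dualnet.forward(np.zeros((1, 1, 64, 64)))


def _stub_dualnet():
    """A Dual-Net with hand-set 1x1-conv stub branches whose full forward is
    computable by hand on a constant input."""
    model = DualNet(DualNetConfig(proj_dim=2, seed=0))
    model.shallow_net = nn.Sequential(nn.Conv2d(3, 2, 1, rng=np.random.default_rng(0)))
    model.deep_net = nn.Sequential(nn.Conv2d(3, 3, 1, rng=np.random.default_rng(0)))
    model.shallow_net.layers[-1].retain = True
    model.deep_net.layers[-1].retain = True
    model.d_s, model.d_d = 2, 3
    model.proj_s = nn.Linear(2, 2)
    model.proj_d = nn.Linear(3, 2)
    model.head_raw = nn.Linear(5, 1)
    model.head_proj = nn.Linear(4, 1)
    # hand-set weights
    cs = model.shallow_net.layers[0]
    cs.weight.data[...] = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
                                   ).reshape(1, 2, 3, 1, 1)
    cs.bias.data[...] = [0.5, -0.25]
    cd = model.deep_net.layers[0]
    cd.weight.data[...] = np.array([[1, 1, 1], [2, 0, 0], [0, 0, -1]],
                                   dtype=float).reshape(1, 3, 3, 1, 1)
    cd.bias.data[...] = [0.0, 1.0, 0.0]
    model.proj_s.weight.data[...] = np.eye(2)
    model.proj_s.bias.data[...] = 0.0
    model.proj_d.weight.data[...] = np.array([[1.0, 0, 0], [0, 1.0, 0]])
    model.proj_d.bias.data[...] = 0.0
    model.head_raw.weight.data[...] = np.array([[0.1, 0.2, 0.3, 0.4, 0.5]])
    model.head_raw.bias.data[...] = -0.1
    return model


class TestForward:
    def test_hand_computed_forward_on_constant_input(self):
        """Brute-force oracle: 1x1 convs on a constant input give constant
        feature maps, so v, the projections, z and the probability follow by
        hand arithmetic."""
        model = _stub_dualnet()
        x = np.full((1, 3, 2, 2), 0.5)
        pair, pred = model.forward(x)
        # shallow: ch0 = 1*0.5 + 0.5 = 1.0 ; ch1 = 1*0.5 - 0.25 = 0.25
        np.testing.assert_allclose(pair.v_s, [[1.0, 0.25]])
        # deep: ch0 = 3*0.5 = 1.5 ; ch1 = 2*0.5 + 1 = 2.0 ; ch2 = -0.5
        np.testing.assert_allclose(pair.v_d, [[1.5, 2.0, -0.5]])
        np.testing.assert_allclose(pair.fhat_s, [[1.0, 0.25]])
        np.testing.assert_allclose(pair.fhat_d, [[1.5, 2.0]])
        # z = [v_d, v_s]; logit = 0.1*1.5+0.2*2+0.3*(-0.5)+0.4*1+0.5*0.25-0.1
        logit = 0.15 + 0.4 - 0.15 + 0.4 + 0.125 - 0.1
        np.testing.assert_allclose(pred.logit, [logit])
        np.testing.assert_allclose(pred.prob, [1 / (1 + np.exp(-logit))])

    def test_zero_weight_head_gives_half(self, tiny_dualnet):
        tiny_dualnet.head_raw.weight.data[...] = 0.0
        tiny_dualnet.head_raw.bias.data[...] = 0.0
        x = np.random.default_rng(3).random((4, 3, 32, 32))
        _, pred = tiny_dualnet.forward(x)
        np.testing.assert_allclose(pred.prob, 0.5)

    def test_batching_order_preserving(self, tiny_dualnet):
        x = np.random.default_rng(4).random((5, 3, 32, 32))
        _, batch_pred = tiny_dualnet.forward(x)
        singles = [tiny_dualnet.forward(x[i:i + 1])[1].prob[0]
                   for i in range(5)]
        np.testing.assert_allclose(batch_pred.prob, singles, rtol=1e-12)

    def test_probability_strictly_inside_unit_interval(self, tiny_dualnet):
        x = np.random.default_rng(5).random((8, 3, 32, 32)) * 10
        _, pred = tiny_dualnet.forward(x)
        assert np.all(pred.prob > 0) and np.all(pred.prob < 1)
        assert np.all(np.isfinite(pred.logit))


class TestVariants:
    def test_variant_head_input_lengths(self, tiny_dualnet):
        x = np.random.default_rng(6).random((1, 3, 32, 32))
        pair_raw, _ = tiny_dualnet.forward(x, variant="concat_raw")
        assert pair_raw.z.shape[1] == tiny_dualnet.d_s + tiny_dualnet.d_d
        pair_proj, _ = tiny_dualnet.forward(x, variant="concat_projected")
        assert pair_proj.z.shape[1] == 2 * tiny_dualnet.config.proj_dim

    def test_variants_agree_with_identity_projections(self):
        """When projections are the identity and the two heads consume the
        same values, the variants produce identical predictions."""
        model = _stub_dualnet()
        model.proj_s = nn.Linear(2, 2)
        model.proj_d = nn.Linear(3, 3)
        model.proj_s.weight.data[...] = np.eye(2)
        model.proj_s.bias.data[...] = 0
        model.proj_d.weight.data[...] = np.eye(3)
        model.proj_d.bias.data[...] = 0
        model.head_proj = nn.Linear(5, 1)
        # z_raw = [v_d, v_s]; z_proj = [fhat_s, fhat_d] = [v_s, v_d]
        w = model.head_raw.weight.data[0]
        model.head_proj.weight.data[...] = np.concatenate([w[3:], w[:3]])[None]
        model.head_proj.bias.data[...] = model.head_raw.bias.data
        x = np.random.default_rng(7).random((3, 3, 4, 4))
        a = classify_variant(model, x, "concat_raw")
        b = classify_variant(model, x, "concat_projected")
        np.testing.assert_allclose(a.prob, b.prob)


class TestTraining:
    def test_gradient_flow_to_every_parameter(self, tiny_dualnet):
        """One joint-loss step sends a nonzero gradient into every trainable
        parameter array of both branches, projections and head."""
        rng = np.random.default_rng(8)
        x = rng.random((8, 3, 32, 32))
        y = rng.integers(0, 2, size=8).astype(float)
        trainer = Trainer(tiny_dualnet, lam=0.3, lr=1e-4, seed=0)
        trainer._opt.zero_grad()
        pair, pred = tiny_dualnet.forward(x)
        from dbtnet.losses import loss_gradients
        g = loss_gradients(pred.prob, y, pair.fhat_s, pair.fhat_d, 0.3)
        tiny_dualnet.backward(*g)
        for p in tiny_dualnet.parameters():
            if p is tiny_dualnet.head_proj.weight or \
                    p is tiny_dualnet.head_proj.bias:
                continue  # unused by the concat_raw variant
            assert np.any(p.grad != 0)

    def test_seeded_determinism_of_loss_trajectory(self):
        rng = np.random.default_rng(9)
        x = rng.random((16, 3, 32, 32))
        y = rng.integers(0, 2, size=16).astype(float)
        histories = []
        for _ in range(2):
            model = DualNet(DualNetConfig(proj_dim=8, seed=3))
            trainer = Trainer(model, lam=0.3, lr=3e-4, batch_size=8, seed=3)
            histories.append([b.total for b in trainer.fit(x, y, epochs=3)])
        assert histories[0] == histories[1]

    def test_learns_separable_toy_task(self):
        """Bright-center vs bright-corner 32x32 images are separable; a short
        training run reaches high slice-level AUC."""
        rng = np.random.default_rng(10)
        n = 60
        x = rng.random((n, 3, 32, 32)).astype(np.float32) * 0.2
        y = (np.arange(n) % 2).astype(float)
        x[y == 1, :, 12:20, 12:20] += 0.7
        x[y == 0, :, 0:8, 0:8] += 0.7
        model = DualNet(DualNetConfig(proj_dim=8, seed=1))
        trainer = Trainer(model, lam=0.3, lr=1e-3, batch_size=16, seed=1)
        trainer.fit(x[:40], y[:40], epochs=20)
        probs = trainer.predict(x[40:])
        assert auc(probs, y[40:]) > 0.9


class TestCheckpoint:
    def test_round_trip(self, tiny_dualnet, tmp_path):
        path = tmp_path / "ckpt.npz"
        tiny_dualnet.save_checkpoint(path)
        restored = DualNet.from_checkpoint(path)
        x = np.random.default_rng(11).random((2, 3, 32, 32))
        _, a = tiny_dualnet.forward(x)
        _, b = restored.forward(x)
        np.testing.assert_array_equal(a.prob, b.prob)
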