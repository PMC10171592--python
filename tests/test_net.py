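import numpy as np
import pytest

from orbitseg.net import (Checkpoint, NetConfig, build_proposed, build_segnet,
                          count_parameters, load_checkpoint, save_checkpoint)

SMALL = NetConfig(widths=(2, 3, 4, 5, 5))


class TestConfig:
    def test_default_matches_vgg_family(self):
        cfg = NetConfig()
        assert cfg.conv_counts == (2, 2, 3, 3, 3)
        assert cfg.widths == (64, 128, 256, 512, 512)
        assert cfg.divisor == 32

    def test_rejects_mismatched_blocks(self):
        with pytest.raises(ValueError):
            NetConfig(conv_counts=(2, 2), widths=(64, 128, 256, 512, 512))
        with pytest.raises(ValueError):
            NetConfig(widths=(64, 0, 256, 512, 512))


class TestShapes:
    def test_output_matches_input_size(self):
        net = build_proposed(SMALL, seed=0)
        for size in (32, 64):
            x = np.zeros((1, size, size, 1), dtype=np.float32)
            assert net.forward(x).shape == (1, size, size, 1)

    def test_bottleneck_and_skip_scales(self):
        net = build_proposed(SMALL, seed=0)
        x = np.random.default_rng(0).random((1, 128, 128, 1), dtype=np.float32)
        net.forward(x)
        skip_sizes = [p.indices.shape[1] * 2 for p in net.enc_pools]
        assert skip_sizes == [128, 64, 32, 16, 8]  # scales 1 .. 1/16
        assert net.enc_pools[-1].indices.shape[1:3] == (4, 4)  # bottleneck 1/32

    def test_rejects_indivisible_input(self):
        net = build_proposed(SMALL, seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 48, 48, 1), dtype=np.float32))

    def test_segnet_shares_shape_contract(self):
        net = build_segnet(SMALL, seed=0)
        x = np.zeros((2, 64, 64, 1), dtype=np.float32)
        assert net.forward(x).shape == (2, 64, 64, 1)


class TestParameterCounts:
    def test_printed_truncated_millions(self):
        assert count_parameters(build_proposed()) // 10**6 == 34
        assert count_parameters(build_segnet()) // 10**6 == 29

    def test_skip_fusion_costs_parameters(self):
        assert count_parameters(build_proposed(SMALL)) > count_parameters(
            build_segnet(SMALL))

    def test_single_conv_accounting(self):
        from orbitseg.nn.layers import Conv2d
        conv = Conv2d("c", 1, 1, 3, np.random.default_rng(0))
        assert sum(p.size for p in conv.params()) == 10  # 9 weights + 1 bias


class TestGradientFlow:
    def test_every_parameter_receives_gradient(self):
        """No dead branches: one backward pass touches all parameters.

        Conv biases directly followed by BatchNorm legitimately have zero
        gradient (BN subtracts the batch mean), so they are exempt.
        """
        net = build_proposed(SMALL, seed=3)
        rng = np.random.default_rng(4)
        x = rng.random((2, 32, 32, 1), dtype=np.float32)
        z = net.forward(x, training=True)
        net.backward(rng.normal(size=z.shape).astype(np.float32))
        names = {p.name for p in net.parameters()}
        for p in net.parameters():
            stem = p.name.rsplit(".bias", 1)[0]
            if p.name.endswith(".bias") and f"{stem}.bn.gamma" in names:
                continue  # bias is absorbed by the following BN's mean
            assert np.any(p.grad != 0), f"no gradient reached {p.name}"

    def test_segnet_ablation_equivalence(self):
        """Zeroing the skip-feature halves of the proposed decoder's first
        convs makes it compute exactly a SegNet forward with shared weights."""
        prop = build_proposed(SMALL, seed=5)
        seg = build_segnet(SMALL, seed=99)
        prop_params = {p.name: p for p in prop.parameters()}
        for p in seg.parameters():
            src = prop_params[p.name]
            if src.value.shape == p.value.shape:
                p.value = src.value.copy()
            else:
                # decoder first conv: keep the unpooled half, drop the skip half
                c = p.value.shape[2]
                p.value = src.value[:, :, :c, :].copy()
                # zero the skip half in the proposed net
                src.value[:, :, c:, :] = 0.0
        x = np.random.default_rng(6).random((1, 32, 32, 1), dtype=np.float32)
        np.testing.assert_allclose(prop.forward(x), seg.forward(x),
                                   rtol=1e-4, atol=1e-5)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path):
        net = build_proposed(SMALL, seed=7)
        x = np.random.default_rng(8).random((1, 32, 32, 1), dtype=np.float32)
        before = net.predict_proba(x)
        ckpt = Checkpoint(state=net.state_dict(), config=net.config,
                          use_skips=True, meta={"note": "test"})
        path = tmp_path / "model.npz"
        save_checkpoint(ckpt, path)
        restored = load_checkpoint(path)
        assert restored.config == net.config
        assert restored.meta["note"] == "test"
        after = restored.build_net().predict_proba(x)
        np.testing.assert_array_equal(before, after)
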