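import numpy as np
import pytest

from endoseg.nn import (
    LayerSpec,
    Network,
    NetworkConfig,
    build_network,
    softmax_cross_entropy,
)


class TestGraphConstruction:
    def test_layer_parameter_counting_toy(self):
        # single dense block of 2 growth convs (3x3, GR 2, input 1 channel, no
        # compression) + output transition (1x1, 2 maps): weights+biases
        # 20 + 56 + 12 = 88, plus 2 scale/shift per channel: 12 -> 100
        specs = [
            LayerSpec("g0", "conv", (), kernel=3, in_channels=1, out_channels=2),
            LayerSpec("b0", "bn", (), out_channels=2),
            LayerSpec("g1", "conv", (), kernel=3, in_channels=3, out_channels=2),
            LayerSpec("b1", "bn", (), out_channels=2),
            LayerSpec("out", "conv", (), kernel=1, in_channels=5, out_channels=2),
            LayerSpec("b2", "bn", (), out_channels=2),
        ]
        assert sum(s.trainable_params for s in specs) == 100

    def test_dense_block_channel_bookkeeping(self):
        g = build_network(NetworkConfig())
        # encoder node at stage a outputs c_in + blocks*GR channels
        assert g["enc0/b3/cat"].out_channels == 1 + 4 * 5
        assert g["enc1/b7/cat"].out_channels == 10 + 8 * 5
        assert g["enc4/b19/cat"].out_channels == 40 + 20 * 5

    def test_construction_is_deterministic(self):
        a = build_network(NetworkConfig(attention="fnla", aggregation="conc"))
        b = build_network(NetworkConfig(attention="fnla", aggregation="conc"))
        assert [l.name for l in a.layers] == [l.name for l in b.layers]
        assert a.total_parameter_count == b.total_parameter_count

    def test_concatenative_attention_widens_channels(self):
        g = build_network(NetworkConfig(attention="fnla", aggregation="conc"))
        c = g["enc2/b11/cat"].out_channels
        assert g["att_enc2/out"].out_channels == c + c // 8

    def test_multiscale_defaults_growth_rate_4(self):
        assert NetworkConfig(multiscale="plusplus").growth_rate == 4
        assert NetworkConfig().growth_rate == 5

    @pytest.mark.parametrize("kw", [
        {"backbone": "unet9"},
        {"multiscale": "plusplusplus"},
        {"aggregation": "div"},
        {"blocks_per_stage": (4, 4, 12, 16, 20)},
        {"stages": 4, "blocks_per_stage": (4, 8, 12, 16)},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            NetworkConfig(**kw)

    def test_summary_totals_match(self):
        g = build_network(NetworkConfig())
        df = g.summary()
        assert df["trainable_params"].sum() == g.trainable_parameter_count
        assert df["total_params"].sum() == g.total_parameter_count


@pytest.fixture(scope="module")
def net16():
    return Network(build_network(NetworkConfig(attention="fnla", aggregation="mul")), seed=0)


class TestEngine:
    def test_forward_shapes_and_softmax_output(self, net16):
        x = np.random.default_rng(0).random((2, 1, 16, 16), np.float32)
        acts = net16.forward(x, training=False)
        out = acts["output"]
        assert out.shape == (2, 2, 16, 16)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-5)

    def test_indivisible_spatial_dims_rejected(self, net16):
        with pytest.raises(ValueError):
            net16.forward(np.zeros((1, 1, 20, 20), np.float32))

    def test_mul_gate_lies_in_open_unit_interval(self, net16):
        x = np.random.default_rng(1).random((1, 1, 16, 16), np.float32)
        acts = net16.forward(x, training=False)
        for name, a in acts.items():
            if name.endswith("/sigmoid"):
                assert (a > 0).all() and (a < 1).all()

    def test_attention_rows_normalized_via_constant_value(self):
        # if V is constant, softmax row-normalization makes Z exactly V
        l = LayerSpec("att", "attend", ("q", "k", "v"), out_channels=3, scale_channels=3)
        rng = np.random.default_rng(2)
        q = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        k = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        v = np.ones((1, 3, 4, 4), np.float32) * np.array([1.0, 2.0, 3.0], np.float32)[None, :, None, None]
        z = Network._attend_fwd(l, q, k, v, {})
        assert np.allclose(z, v, atol=1e-5)

    def test_attention_single_position_returns_value(self):
        l = LayerSpec("att", "attend", ("q", "k", "v"), out_channels=2, scale_channels=2)
        q = np.random.default_rng(3).normal(size=(1, 2, 1, 1)).astype(np.float32)
        k = np.random.default_rng(4).normal(size=(1, 2, 1, 1)).astype(np.float32)
        v = np.array([[[[0.7]], [[-1.2]]]], np.float32)
        z = Network._attend_fwd(l, q, k, v, {})
        assert np.allclose(z, v, atol=1e-6)

    def test_gradients_match_finite_differences(self, net16):
        rng = np.random.default_rng(5)
        x = rng.random((1, 1, 16, 16), np.float32)
        t = rng.random((1, 2, 16, 16), np.float32)
        t /= t.sum(axis=1, keepdims=True)

        def loss_fn():
            acts = net16.forward(x, training=False)
            return softmax_cross_entropy(acts["logits"], t)[0]

        acts = net16.forward(x, training=False)
        loss, dlog = softmax_cross_entropy(acts["logits"], t)
        grads = net16.backward(dlog)
        for name in ["head/conv", "enc1/b2/growth/conv", "att_dec1/omega"]:
            p = net16.params[name]["W"]
            idx = tuple(0 for _ in p.shape)
            eps = 1e-3
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss_fn()
            p[idx] = orig - eps
            lm = loss_fn()
            p[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            analytic = grads[name]["W"][idx]
            assert analytic == pytest.approx(numeric, abs=2e-4, rel=0.1)

    def test_checkpoint_roundtrip(self, net16, tmp_path):
        x = np.random.default_rng(6).random((1, 1, 16, 16), np.float32)
        before = net16.forward(x, training=False)["output"]
        path = tmp_path / "w.npz"
        net16.save(path)
        other = Network(net16.graph, seed=99)
        other.load(path)
        after = other.forward(x, training=False)["output"]
        assert np.allclose(before, after)


class TestLoss:
    def test_uniform_predictor_scores_ln2(self):
        logits = np.zeros((1, 2, 8, 8), np.float32)
        target = np.zeros((1, 2, 8, 8), np.float32)
        target[:, 0] = 1.0
        loss, grad = softmax_cross_entropy(logits, target)
        assert loss == pytest.approx(np.log(2.0), rel=1e-6)

    def test_gradient_vanishes_at_perfect_prediction(self):
        logits = np.zeros((1, 2, 4, 4), np.float32)
        logits[:, 0] = 20.0
        target = np.zeros((1, 2, 4, 4), np.float32)
        target[:, 0] = 1.0
        loss, grad = softmax_cross_entropy(logits, target)
        assert loss < 1e-6 and np.abs(grad).max() < 1e-6
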