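"""Residual units, hybrid attention, network contracts, training behavior."""

import numpy as np
import pytest

from har_locator.harnet import (
    ConfigurationError,
    HARnet,
    HarnetConfig,
    HybridAttention,
    HybridAttentionConfig,
    ResidualUnit,
    TrainConfig,
    _as_batch,
    build_harnet,
    extract_multiview,
    train_harnet,
)
from har_locator.nn import BatchNorm2d, Conv2d, Linear, softmax, softmax_cross_entropy
from oracles import attention_h3_bruteforce


def _zero_attention(att):
    for lay in (att.p11, att.p21):
        lay.w.data[...] = 0
        lay.b.data[...] = 0
    for lay in (att.p12, att.p22):
        lay.w.data[...] = 0
        lay.b.data[...] = 0


class TestGradients:
    """Numerical gradient checks of the engine primitives (float64)."""

    @pytest.mark.parametrize(
        "make",
        [
            lambda rng: Conv2d(2, 3, 3, stride=2, rng=rng, dtype=np.float64),
            lambda rng: Linear(8, 4, rng=rng, dtype=np.float64),
        ],
    )
    def test_parameter_gradients(self, make, rng):
        layer = make(rng)
        x = rng.standard_normal((2, 2, 6, 6))
        if isinstance(layer, Linear):
            x = rng.standard_normal((3, 8))
        tgt = rng.standard_normal(layer.forward(x).shape)

        def loss():
            return 0.5 * np.sum((layer.forward(x) - tgt) ** 2)

        layer.forward(x)
        dout = layer.forward(x) - tgt
        for p in layer.params():
            p.grad[...] = 0
        dx = layer.backward(dout)
        eps = 1e-6
        # parameter gradient spot checks
        for p in layer.params():
            flat = p.data.ravel()
            for k in (0, flat.size // 2, flat.size - 1):
                old = flat[k]
                flat[k] = old + eps
                lp = loss()
                flat[k] = old - eps
                lm = loss()
                flat[k] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - p.grad.ravel()[k]) < 1e-4 * max(1, abs(num))
        # input gradient spot check
        xf = x.ravel()
        for k in (0, xf.size - 1):
            old = xf[k]
            xf[k] = old + eps
            lp = loss()
            xf[k] = old - eps
            lm = loss()
            xf[k] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - dx.ravel()[k]) < 1e-4 * max(1, abs(num))

    def test_batchnorm_train_gradient(self, rng):
        bn = BatchNorm2d(3, dtype=np.float64)
        x = rng.standard_normal((4, 3, 5, 5))
        tgt = rng.standard_normal(x.shape)

        def loss(inp):
            return 0.5 * np.sum((bn.forward(inp, train=True) - tgt) ** 2)

        dout = bn.forward(x, train=True) - tgt
        dx = bn.backward(dout)
        eps = 1e-6
        for k in (0, x.size // 3, x.size - 1):
            xf = x.ravel()
            old = xf[k]
            xf[k] = old + eps
            lp = loss(x)
            xf[k] = old - eps
            lm = loss(x)
            xf[k] = old
            num = (lp - lm) / (2 * eps)
            assert abs(num - dx.ravel()[k]) < 1e-4 * max(1, abs(num))


class TestResidualUnit:
    def test_zero_conv_weights_is_identity(self, rng):
        ru = ResidualUnit(8, 8, rng=rng)
        ru.conv2.w.data[...] = 0
        ru.conv2.b.data[...] = 0
        x = rng.standard_normal((2, 8, 12, 12)).astype(np.float32)
        assert np.array_equal(ru.forward(x), x)

    def test_shape_preserved_stride1(self, rng):
        ru = ResidualUnit(8, 8, rng=rng)
        x = rng.standard_normal((2, 8, 12, 12)).astype(np.float32)
        assert ru.forward(x).shape == x.shape

    def test_projection_shapes(self, rng):
        ru = ResidualUnit(8, 16, stride=2, rng=rng)
        x = rng.standard_normal((2, 8, 12, 12)).astype(np.float32)
        assert ru.forward(x).shape == (2, 16, 6, 6)

    def test_gradient_flows_through_shortcut_with_zero_convs(self, rng):
        ru = ResidualUnit(4, 4, rng=rng)
        for conv in (ru.conv1, ru.conv2):
            conv.w.data[...] = 0
            conv.b.data[...] = 0
        x = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        ru.forward(x, train=False)
        dx = ru.backward(np.ones_like(x))
        assert np.abs(dx).max() > 0


class TestHybridAttention:
    @pytest.mark.parametrize("variant", ["H1", "H2", "H3"])
    def test_output_shape_equals_input(self, variant, rng):
        att = HybridAttention(HybridAttentionConfig(variant, 64, 4), rng=rng)
        x = rng.standard_normal((1, 64, 32, 32)).astype(np.float32)
        assert att.forward(x).shape == x.shape

    def test_zero_logits_halve_identity_branch(self, rng):
        att = HybridAttention(HybridAttentionConfig("H3", 8, 4), rng=rng)
        _zero_attention(att)
        x = rng.standard_normal((2, 8, 10, 10)).astype(np.float32)
        assert np.array_equal(att.forward(x), 0.5 * x)

    def test_zero_logits_h2_is_half_bottom_branch(self, rng):
        att = HybridAttention(HybridAttentionConfig("H2", 8, 4), rng=rng)
        _zero_attention(att)
        x = rng.standard_normal((1, 8, 16, 16)).astype(np.float32)
        out = att.forward(x)
        b = att.bottom.forward(x)
        np.testing.assert_allclose(out, 0.5 * b, rtol=1e-6)

    def test_gate_bounds_output(self, rng):
        """sigmoid gate in (0,1) implies |X'| <= |B(X)| elementwise."""
        att = HybridAttention(HybridAttentionConfig("H3", 16, 4), rng=rng)
        x = rng.standard_normal((2, 16, 8, 8)).astype(np.float32)
        out = att.forward(x)
        assert np.all(np.abs(out) <= np.abs(x) + 1e-6)

    def test_matches_straight_line_equations(self, rng):
        """Hand transcription of the attention equations (identity bottom
        branch, 1-channel 4x4 input, reduction 1) within 1e-6."""
        att = HybridAttention(HybridAttentionConfig("H3", 1, 1), rng=rng)
        for lay in (att.p11, att.p21):
            lay.w.data = rng.uniform(-0.5, 0.5, lay.w.data.shape).astype(np.float32)
            lay.b.data = rng.uniform(-0.1, 0.1, lay.b.data.shape).astype(np.float32)
        for lay in (att.p12, att.p22):
            lay.w.data = rng.uniform(-0.5, 0.5, lay.w.data.shape).astype(np.float32)
            lay.b.data = rng.uniform(-0.1, 0.1, lay.b.data.shape).astype(np.float32)
        x = rng.uniform(-1, 1, (1, 1, 4, 4)).astype(np.float32)
        out = att.forward(x)[0]
        ref = attention_h3_bruteforce(
            x[0].astype(float),
            att.p11.w.data.reshape(1, 1).astype(float),
            att.p11.b.data.astype(float),
            att.p21.w.data.reshape(1, 1).astype(float),
            att.p21.b.data.astype(float),
            att.p12.w.data.T.astype(float),
            att.p12.b.data.astype(float),
            att.p22.w.data.T.astype(float),
            att.p22.b.data.astype(float),
        )
        np.testing.assert_allclose(out, ref, atol=1e-6)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ConfigurationError):
            HybridAttentionConfig("H2", 6, 4)


class TestBuild:
    def test_forward_probabilities_sum_to_one(self):
        model = build_harnet(HarnetConfig.tiny(seed=0))
        x = np.zeros((128, 128, 3), np.uint8)
        p = softmax(model.forward(_as_batch([x])))
        assert p.shape == (1, 7)
        assert abs(p.sum() - 1.0) < 1e-6

    def test_tap_widths_match_config(self):
        cfg = HarnetConfig.tiny(seed=0)
        model = build_harnet(cfg)
        mv = extract_multiview(model, np.zeros((128, 128, 3), np.uint8))
        assert mv.h1.shape == (cfg.stage_widths[0],)
        assert mv.h2.shape == (cfg.stage_widths[1],)
        assert mv.h3.shape == (cfg.stage_widths[2],)
        assert mv.g.shape == (cfg.final_width,)

    def test_same_seed_identical_parameters(self):
        a = build_harnet(HarnetConfig.tiny(seed=5))
        b = build_harnet(HarnetConfig.tiny(seed=5))
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.data, pb.data)

    def test_bad_input_size_rejected(self):
        with pytest.raises(ConfigurationError):
            build_harnet(HarnetConfig(input_size=100))

    def test_inference_deterministic(self):
        model = build_harnet(HarnetConfig.tiny(seed=0))
        img = np.random.default_rng(0).integers(0, 255, (128, 128, 3), dtype=np.uint8)
        a = extract_multiview(model, img)
        b = extract_multiview(model, img)
        for k in ("h1", "h2", "h3", "g"):
            assert np.array_equal(a.tap(k), b.tap(k))


class TestTraining:
    def test_lr_schedule_single_step_drop(self):
        t = TrainConfig()
        assert t.lr_at(0) == 1e-3
        assert t.lr_at(59) == 1e-3
        assert t.lr_at(60) == pytest.approx(1e-4)  # the 61st epoch
        assert t.lr_at(299) == pytest.approx(1e-4)

    def test_label_out_of_range_rejected(self):
        model = build_harnet(HarnetConfig.tiny(seed=0))
        imgs = [np.zeros((128, 128, 3), np.uint8)]
        with pytest.raises(ValueError):
            train_harnet(model, imgs, [9], TrainConfig(epochs=1))
        with pytest.raises(ValueError):
            train_harnet(model, [], [], TrainConfig(epochs=1))

    def test_loss_decreases_and_features_become_separable(self, separable_training):
        """Training on well-separated synthetic classes drives the loss down
        and reaches high training accuracy (generator separability oracle)."""
        history = separable_training["history"]
        assert history["loss"][2] < history["loss"][0]
        assert max(history["accuracy"]) >= 0.95

    def test_multiview_features_support_linear_classifier(self, separable_training):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        feats = separable_training["mvf"]
        labels = separable_training["labels"]
        X = np.hstack([feats[k] for k in ("h1", "h2", "h3", "g")])
        acc = cross_val_score(LogisticRegression(max_iter=2000), X, labels, cv=3).mean()
        assert acc >= 0.90


@pytest.fixture(scope="session")
def separable_training():
    """Train a tiny HARnet once on 42 well-separated synthetic images."""
    from har_locator.harnet import extract_multiview_batch
    from har_locator.preprocess import preprocess_image
    from har_locator.synthetic import SynthConfig, generate_dataset

    samples = generate_dataset(SynthConfig(n_per_class=10, image_size=128, seed=3))
    rgbs = [preprocess_image(s.image, input_size=128)[0] for s in samples]
    labels = np.array([s.label for s in samples])
    model = build_harnet(HarnetConfig.tiny(seed=0))
    tcfg = TrainConfig(epochs=30, batch_size=8, seed=0)
    # early stop once the separability target is reached, epoch granularity
    history = {"loss": [], "accuracy": [], "lr": []}
    for epoch in range(tcfg.epochs):
        sub = TrainConfig(epochs=1, batch_size=8, seed=epoch,
                          initial_lr=tcfg.lr_at(epoch))
        h = train_harnet(model, rgbs, labels, sub)
        for k in history:
            history[k].extend(h[k])
        if history["accuracy"][-1] >= 0.95 and epoch >= 7:
            break
    mvf = extract_multiview_batch(model, rgbs)
    return {"history": history, "mvf": mvf, "labels": labels, "model": model}
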