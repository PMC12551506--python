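import numpy as np
import pytest

from ontoquant.encoder import encode_corpus, small_config, tokenize_batch
from ontoquant.errors import SchemeCombinationError, ValidationError
from ontoquant.quantcore import (PER_TENSOR, ActivationStats, SmoothingConfig,
                                 apply_smoothing, collect_activation_stats,
                                 compute_smoothing_scales, dequantize,
                                 load_quantized, per_channel,
                                 qlinear_elementwise, qlinear_matmul, quantize,
                                 quantize_encoder, save_quantized)


class TestQuantizeDequantize:
    def test_per_tensor_example(self):
        t = quantize(np.array([1.0, -0.5, 0.25]))
        assert t.scales == pytest.approx(1 / 127)
        # -63.5 rounds half-to-even to -64; 31.75 to 32
        assert t.q.tolist() == [127, -64, 32]

    def test_all_zero_tensor(self):
        t = quantize(np.zeros(4), epsilon=1e-12)
        assert t.q.tolist() == [0, 0, 0, 0]
        assert t.scales == 1e-12
        assert np.all(dequantize(t) == 0)

    def test_per_channel_column_scales(self):
        W = np.array([[1.0, 0.1], [-2.0, 0.05]])
        t = quantize(W, per_channel(axis=1))
        np.testing.assert_allclose(t.scales, [2 / 127, 0.1 / 127])

    def test_dequantize_example(self):
        t = quantize(np.array([1.0, -0.5, 0.25]))
        np.testing.assert_allclose(dequantize(t),
                                   np.array([127, -64, 32]) / 127)

    def test_round_trip_bound(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(scale=rng.uniform(0.1, 10), size=(7, 5))
            for scheme in (PER_TENSOR, per_channel(0), per_channel(1)):
                t = quantize(x, scheme)
                step = np.broadcast_to(
                    np.asarray(t.broadcast_scales()), x.shape)
                err = np.abs(x - dequantize(t))
                assert np.all(err <= step / 2 + 1e-12)

    def test_per_channel_beats_per_tensor_frobenius(self):
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            # heterogeneous column magnitudes, where granularity matters
            W = rng.normal(size=(8, 6)) * rng.uniform(0.01, 5, size=6)
            e_pc = np.linalg.norm(W - dequantize(quantize(W, per_channel(1))))
            e_pt = np.linalg.norm(W - dequantize(quantize(W, PER_TENSOR)))
            assert e_pc <= e_pt + 1e-12

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            quantize(np.array([1.0, np.inf]))


class TestQLinearMatmul:
    def test_hand_worked_example(self):
        xq = quantize(np.array([[1.0, -1.0]]))
        Wq = quantize(np.array([[1.0], [-2.0]]), per_channel(1))
        y = qlinear_matmul(xq, Wq)
        # y_int = 127*64 + (-127)(-127) = 24257, scales (1/127)(2/127)
        assert y[0, 0] == pytest.approx(24257 / 127 * 2 / 127)
        expected = dequantize(xq) @ dequantize(Wq)
        np.testing.assert_allclose(y, expected, rtol=1e-12)

    def test_zero_activation(self):
        xq = quantize(np.zeros((2, 3)))
        Wq = quantize(np.ones((3, 4)), per_channel(1))
        assert np.all(qlinear_matmul(xq, Wq) == 0)

    def test_equals_dequantized_product(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(4, 6))
            W = rng.normal(size=(6, 5))
            xq, Wq = quantize(x), quantize(W, per_channel(1))
            got = qlinear_matmul(xq, Wq)
            want = dequantize(xq) @ dequantize(Wq)
            np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_per_channel_activations_rejected(self):
        xq = quantize(np.ones((2, 3)), per_channel(1))
        Wq = quantize(np.ones((3, 4)), per_channel(1))
        with pytest.raises(SchemeCombinationError):
            qlinear_matmul(xq, Wq)

    def test_contraction_axis_weight_scales_rejected(self):
        xq = quantize(np.ones((2, 3)))
        Wq = quantize(np.ones((3, 4)), per_channel(0))
        with pytest.raises(SchemeCombinationError):
            qlinear_matmul(xq, Wq)


class TestQLinearElementwise:
    def test_relu(self):
        np.testing.assert_array_equal(
            qlinear_elementwise(np.array([-1.0, 2.0]), op="relu"), [0.0, 2.0])

    def test_add_identity(self):
        t = quantize(np.array([0.3, -0.7]))
        np.testing.assert_allclose(qlinear_elementwise(t, np.zeros(2), "add"),
                                   dequantize(t))

    def test_add_of_negation_within_one_step(self):
        x = np.array([0.91, -0.33, 0.5])
        t, tn = quantize(x), quantize(-x)
        out = qlinear_elementwise(t, tn, "add")
        assert np.all(np.abs(out) <= float(t.scales) + float(tn.scales))

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            qlinear_elementwise(np.ones(3), np.ones(4), "add")


class _StubEncoder:
    def __init__(self, activations):
        self._acts = activations

    def linear_inputs(self, texts):
        return self._acts


class TestCalibrationAndSmoothing:
    def test_stats_columnwise_maxabs(self):
        stub = _StubEncoder([np.array([[1.0, -3.0], [2.0, 0.5]])])
        (stats,) = collect_activation_stats(stub, ["x"])
        np.testing.assert_allclose(stats.per_channel_maxabs, [2.0, 3.0])
        assert stats.n_samples == 2

    def test_stats_zero_row(self):
        stub = _StubEncoder([np.zeros((1, 3))])
        (stats,) = collect_activation_stats(stub, ["x"])
        assert np.all(stats.per_channel_maxabs == 0)

    def test_empty_calibration_rejected(self, tiny_encoder):
        with pytest.raises(ValidationError):
            collect_activation_stats(tiny_encoder, [])

    def test_stats_permutation_invariant(self, tiny_encoder):
        texts = ["alpha beta", "gamma delta eps", "zeta"]
        a = collect_activation_stats(tiny_encoder, texts)
        b = collect_activation_stats(tiny_encoder, texts[::-1])
        for sa, sb in zip(a, b):
            np.testing.assert_allclose(sa.per_channel_maxabs,
                                       sb.per_channel_maxabs)
            np.testing.assert_allclose(sa.per_channel_variance,
                                       sb.per_channel_variance, atol=1e-12)

    def test_smoothing_scale_formula(self):
        stats = ActivationStats(np.array([4.0]), np.array([0.0]), 1)
        W = np.array([[0.25]])
        s = compute_smoothing_scales(stats, W, SmoothingConfig(alpha=0.5))
        assert s[0] == pytest.approx(4.0)
        s0 = compute_smoothing_scales(stats, W, SmoothingConfig(alpha=0.0))
        assert s0[0] == pytest.approx(1 / 0.25)

    def test_smoothing_scale_symmetry_gives_ones(self):
        stats = ActivationStats(np.array([0.7, 2.0]), np.zeros(2), 1)
        W = np.array([[0.7, -0.1], [2.0, 1.0]])
        s = compute_smoothing_scales(stats, W, SmoothingConfig(alpha=0.5))
        np.testing.assert_allclose(s, [1.0, 1.0])

    def test_apply_smoothing_identity_and_ranges(self):
        X = np.array([[4.0, 1.0]])
        W = np.array([[0.25, 0.1], [1.0, 0.5]])
        Xs, Ws = apply_smoothing(X, W, np.ones(2))
        np.testing.assert_array_equal(Xs, X)
        np.testing.assert_array_equal(Ws, W)
        Xs, Ws = apply_smoothing(X, W, np.array([4.0, 1.0]))
        assert np.abs(Xs[:, 0]).max() == pytest.approx(1.0)
        assert np.abs(Ws[0]).max() == pytest.approx(1.0)

    def test_smoothing_product_exact(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(5, 8))
            W = rng.normal(size=(8, 4))
            s = rng.uniform(0.1, 10, size=8)
            Xs, Ws = apply_smoothing(X, W, s)
            err = np.abs(Xs @ Ws - X @ W).max()
            assert err <= 1e-6 * max(np.abs(X @ W).max(), 1e-30)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValidationError):
            apply_smoothing(np.ones((1, 2)), np.ones((2, 2)),
                            np.array([1.0, 0.0]))

    def test_outlier_redistribution(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 16))
        X[:, 3] *= 100.0  # one outlier channel
        W = rng.normal(size=(16, 16))
        stats = ActivationStats(np.abs(X).max(0), X.var(0), 50)
        s = compute_smoothing_scales(stats, W, SmoothingConfig(alpha=0.5))
        Xs, _ = apply_smoothing(X, W, s)
        before = np.abs(X).max(0)
        after = np.abs(Xs).max(0)
        assert (after.max() / np.median(after)
                < before.max() / np.median(before))


class TestQuantizedEncoder:
    def test_embedding_cosine_close_to_fp32(self, default_encoder):
        texts = [f"token{i} alpha beta c{i}" for i in range(12)]
        qenc = quantize_encoder(default_encoder, texts,
                                smoothing=SmoothingConfig(alpha=0.5))
        ef = encode_corpus(texts, default_encoder).e
        eq = encode_corpus(texts, qenc).e
        cos = (np.sum(ef * eq, axis=1)
               / np.linalg.norm(ef, axis=1) / np.linalg.norm(eq, axis=1))
        assert cos.min() >= 0.99

    def test_weight_payload_under_30_percent(self, default_encoder):
        qenc = quantize_encoder(default_encoder, ["calibration text"],
                                smoothing=SmoothingConfig())
        ratio = qenc.weight_payload_bytes() / default_encoder.weight_payload_bytes()
        assert ratio <= 0.30

    def test_archive_round_trip(self, tmp_path, tiny_encoder):
        texts = ["alpha beta", "gamma delta"]
        qenc = quantize_encoder(tiny_encoder, texts,
                                smoothing=SmoothingConfig(alpha=0.5))
        path = tmp_path / "q.npz"
        save_quantized(qenc, path)
        loaded = load_quantized(path)
        batch = tokenize_batch(texts, tiny_encoder.config)
        np.testing.assert_allclose(loaded.hidden_states(batch),
                                   qenc.hidden_states(batch),
                                   rtol=0, atol=1e-6)
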