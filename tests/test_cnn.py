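import numpy as np
import pytest

import oracles
from nodulefuse.cnn import (
    CNNSpec,
    ConvSpec,
    PoolSpec,
    ReluSpec,
    SmallCNNClassifier,
    TrainConfig,
    build_default_spec,
    conv2d_forward,
    forward,
    train,
)

TINY_SPEC = CNNSpec(
    layers=(ConvSpec(2, 3), ReluSpec(), PoolSpec(2, 2)),
    input_size=6,
    output_classes=2,
)


def _bright_dark_patches(n=40, size=50, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    bright = 0.9 + rng.normal(0, 0.02, (half, size, size))
    dark = 0.1 + rng.normal(0, 0.02, (n - half, size, size))
    X = np.clip(np.concatenate([bright, dark]), 0, 1)
    y = np.array(["nodule"] * half + ["nonnodule"] * (n - half))
    return X, y


class TestArchitecture:
    def test_default_spatial_trace(self):
        assert build_default_spec().spatial_trace() == [50, 46, 23, 19, 9, 5, 5, 4, 1]

    def test_default_feature_dim_is_40(self):
        assert build_default_spec().feature_dim == 40

    def test_first_conv_layer_geometry(self):
        first = build_default_spec().layers[0]
        assert isinstance(first, ConvSpec)
        assert first.filters == 20 and first.kernel == 5

    def test_valid_convolution_arithmetic(self):
        # conv(20 @ 5x5) on 50x50 -> 46x46x20
        model = SmallCNNClassifier(random_state=0).initialize()
        conv1 = model.network_.feature_layers[0]
        out = conv1.forward(np.zeros((1, 1, 50, 50), dtype=np.float32), train=False)
        assert out.shape == (1, 20, 46, 46)

    def test_non_composing_spec_rejected(self):
        bad = CNNSpec(layers=(ConvSpec(4, 9),), input_size=6)
        with pytest.raises(ValueError):
            bad.spatial_trace()


class TestForward:
    def test_probabilities_sum_to_one(self, rng):
        model = SmallCNNClassifier(random_state=1).initialize()
        probs = model.predict_proba(rng.uniform(0, 1, (7, 50, 50)))
        assert probs.shape == (7, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
        assert (probs >= 0).all()

    def test_zero_parameters_give_uniform_probs_and_zero_features(self, rng):
        model = SmallCNNClassifier(random_state=0).initialize()
        for param, _ in model.network_.parameters():
            param[...] = 0.0
        patch = rng.uniform(0, 1, (50, 50))
        probs, feats = forward(model, patch)
        np.testing.assert_allclose(probs, [0.5, 0.5], atol=1e-12)
        np.testing.assert_array_equal(feats, np.zeros(40))

    def test_feature_vector_length_40(self, rng):
        model = SmallCNNClassifier(random_state=0).initialize()
        feats = model.transform(rng.uniform(0, 1, (3, 50, 50)))
        assert feats.shape == (3, 40)

    def test_conv_layer_matches_quadruple_loop_oracle(self, rng):
        x = rng.normal(size=(2, 3, 6, 6))
        W = rng.normal(size=(4, 3, 3, 3))
        b = rng.normal(size=4)
        np.testing.assert_allclose(conv2d_forward(x, W, b),
                                   oracles.conv_oracle(x, W, b), atol=1e-10)

    def test_hand_computed_single_channel_convolution(self):
        # 3x3 averaging-like kernel on a 4x4 ramp, checked by hand
        x = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        W = np.zeros((1, 1, 3, 3))
        W[0, 0, 1, 1] = 2.0  # pure centre tap doubles the centre pixel
        out = conv2d_forward(x, W, np.array([1.0]))
        np.testing.assert_allclose(out[0, 0], 2.0 * x[0, 0, 1:3, 1:3] + 1.0)

    def test_shape_mismatch_rejected(self, rng):
        model = SmallCNNClassifier(random_state=0).initialize()
        with pytest.raises(ValueError):
            model.predict_proba(rng.uniform(0, 1, (2, 40, 40)))


class TestGradients:
    def test_analytic_gradients_match_central_differences(self, rng):
        model = SmallCNNClassifier(spec=TINY_SPEC, random_state=3,
                                   dtype="float64").initialize(["a", "b"])
        x = rng.uniform(0, 1, (5, 6, 6))
        xin = model._as_input(x)
        y_idx = np.array([0, 1, 0, 1, 1])
        model._loss_and_grads(xin, y_idx)
        analytic = [(p, g.copy()) for p, g in model.network_.parameters()]
        eps = 1e-6
        for param, grad in analytic:
            flat_p = param.ravel()
            flat_g = grad.ravel()
            for i in range(flat_p.size):
                orig = flat_p[i]
                flat_p[i] = orig + eps
                plus, _ = model._loss_and_grads(xin, y_idx)
                flat_p[i] = orig - eps
                minus, _ = model._loss_and_grads(xin, y_idx)
                flat_p[i] = orig
                numeric = (plus - minus) / (2 * eps)
                denom = max(abs(numeric) + abs(flat_g[i]), 1e-4)
                assert abs(numeric - flat_g[i]) / denom < 1e-4, (
                    f"gradient mismatch at index {i}: {numeric} vs {flat_g[i]}"
                )


class TestTraining:
    def test_separable_patches_reach_perfect_accuracy(self):
        X, y = _bright_dark_patches()
        model = SmallCNNClassifier(max_iter=200, random_state=0).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_seeded_determinism(self):
        X, y = _bright_dark_patches(n=20)
        a = SmallCNNClassifier(max_iter=30, random_state=5).fit(X, y)
        b = SmallCNNClassifier(max_iter=30, random_state=5).fit(X, y)
        np.testing.assert_array_equal(a.loss_trace_, b.loss_trace_)
        assert a.loss_trace_[-1] == b.loss_trace_[-1]

    def test_full_batch_loss_non_increasing(self):
        X, y = _bright_dark_patches(n=16)
        model = SmallCNNClassifier(max_iter=30, batch_size=16,
                                   learning_rate=0.005, random_state=2).fit(X, y)
        checkpoints = model.loss_trace_[[0, 14, 29]]
        assert checkpoints[0] >= checkpoints[1] >= checkpoints[2]

    def test_single_class_data_rejected(self):
        X = np.zeros((4, 50, 50))
        with pytest.raises(ValueError):
            SmallCNNClassifier(max_iter=5).fit(X, ["nodule"] * 4)

    def test_train_wrapper_returns_trace(self):
        X, y = _bright_dark_patches(n=12)
        model, trace = train(X, y, TrainConfig(max_iterations=10, seed=0))
        assert model.n_iter_ == 10
        assert trace.shape == (10,)

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1).validate()


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        X, y = _bright_dark_patches(n=12)
        model = SmallCNNClassifier(max_iter=10, random_state=0).fit(X, y)
        path = tmp_path / "params.npz"
        model.save_params(path)
        clone = SmallCNNClassifier().load_params(path)
        probe = rng.uniform(0, 1, (3, 50, 50))
        np.testing.assert_array_equal(model.predict_proba(probe),
                                      clone.predict_proba(probe))
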