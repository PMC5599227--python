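import numpy as np
import pytest

from nirsbci.exceptions import ArchitectureError, DivergenceError
from nirsbci.models import (
    ANNSpec,
    CNNSpec,
    SVMSpec,
    TrainConfig,
    build_ann,
    build_cnn,
    cnn_shape_propagation,
    pca_fit,
    pca_transform,
    predict,
    train_ann,
    train_cnn,
    train_svm,
)
from nirsbci.models.nn import Conv1dSame, MaxPool1d, ReLU, softmax


class TestShapePropagation:
    def test_cnn2a_matches_reference_table(self):
        """Shape propagation of the three-conv-layer, 32-filter structure on
        a 257 x 68 input, layer by layer."""
        rows = cnn_shape_propagation(CNNSpec.named("CNN2-a"), (257, 68))
        expected = [
            ("Convolutional layer 1", (257, 68), (257, 32)),
            ("Max-pooling 1", (257, 32), (128, 32)),
            ("Dropout 1", (128, 32), (128, 32)),
            ("Convolutional layer 2", (128, 32), (128, 32)),
            ("Max-pooling 2", (128, 32), (64, 32)),
            ("Dropout 2", (64, 32), (64, 32)),
            ("Convolutional layer 3", (64, 32), (64, 32)),
            ("Max-pooling 3", (64, 32), (32, 32)),
            ("Dropout 3", (32, 32), (32, 32)),
            ("Fully connected layer 1", (1024,), (256,)),
            ("Fully connected layer 2", (256,), (128,)),
            ("Output layer", (128,), (3,)),
        ]
        assert rows == expected

    def test_degenerate_input_raises_architecture_error(self):
        with pytest.raises(ArchitectureError, match="collapses"):
            cnn_shape_propagation(CNNSpec.named("CNN2-a"), (4, 68))

    def test_forward_pass_shapes_match_propagation(self):
        net = build_cnn(CNNSpec.named("CNN2-a"), (257, 68), seed=0)
        x = np.random.default_rng(0).standard_normal((2, 257, 68))
        out = net.forward(x)
        assert out.shape == (2, 3)
        # first conv block output
        conv_out = net.layers[0].forward(x, False, None)
        assert conv_out.shape == (2, 257, 32)


class TestPrimitives:
    def test_relu(self):
        relu = ReLU()
        out = relu.forward(np.array([[-2.0, 3.0]]), False, None)
        np.testing.assert_array_equal(out, [[0.0, 3.0]])

    def test_maxpool_257_to_128(self):
        pool = MaxPool1d(2)
        x = np.random.default_rng(0).standard_normal((1, 257, 4))
        assert pool.forward(x, False, None).shape == (1, 128, 4)

    def test_maxpool_values(self):
        pool = MaxPool1d(2)
        x = np.array([[[1.0], [5.0], [2.0], [3.0], [9.0]]])
        np.testing.assert_array_equal(
            pool.forward(x, False, None), [[[5.0], [3.0]]])

    def test_convolution_matches_sliding_dot_product(self):
        """Brute-force oracle: out[i, f] = sum_{u, c} W[u, c, f] * xpad[i+u, c]
        with zero padding, on random 20 x 4 inputs."""
        rng = np.random.default_rng(5)
        conv = Conv1dSame(c_in=4, n_filters=3, kernel_size=3, rng=rng)
        x = rng.standard_normal((2, 20, 4))
        got = conv.forward(x, False, None)
        w = conv.kernel  # (3, 4, 3)
        xpad = np.pad(x, ((0, 0), (1, 1), (0, 0)))
        expected = np.zeros((2, 20, 3))
        for b in range(2):
            for i in range(20):
                for f in range(3):
                    acc = conv.b[f]
                    for u in range(3):
                        for c in range(4):
                            acc += w[u, c, f] * xpad[b, i + u, c]
                    expected[b, i, f] = acc
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_conv_gradient_check(self):
        rng = np.random.default_rng(6)
        conv = Conv1dSame(c_in=2, n_filters=2, kernel_size=3, rng=rng)
        x = rng.standard_normal((1, 7, 2))
        out = conv.forward(x, False, None)
        g = rng.standard_normal(out.shape)
        gx = conv.backward(g)
        eps = 1e-6
        for idx in [(0, 0, 0), (0, 3, 1), (0, 6, 0)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = (np.sum(conv.forward(xp, False, None) * g)
                   - np.sum(conv.forward(xm, False, None) * g)) / (2 * eps)
            assert gx[idx] == pytest.approx(num, rel=1e-5)

    def test_softmax_rows_sum_to_one(self):
        probs = softmax(np.random.default_rng(0).standard_normal((5, 3)) * 10)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)


def _separable_features(n=200, d=20, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array(["rest", "right", "left"])[rng.integers(0, 3, n)]
    centers = {"rest": 0.0, "right": 3.0, "left": -3.0}
    x = rng.standard_normal((n, d)) * 0.3
    x[:, 0] += np.array([centers[l] for l in labels])
    return x, labels


class TestANN:
    def test_untrained_softmax_sums_to_one(self):
        net = build_ann(ANNSpec.named("ANN1-a"), n_features=24, seed=0)
        probs = net.predict_proba(np.random.default_rng(0).standard_normal((4, 24)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_weight_net_uniform_probabilities(self):
        net = build_ann(ANNSpec.named("ANN1-a"), n_features=10, seed=0)
        for p in net.parameters():
            p[:] = 0.0
        probs = net.predict_proba(np.ones((3, 10)))
        np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-12)

    def test_separable_training_accuracy(self):
        x, y = _separable_features()
        clf = train_ann(x, y, ANNSpec.named("ANN1-a"),
                        TrainConfig(epochs=100, batch_size=16,
                                    learning_rate=1e-3, seed=0))
        acc = np.mean(clf.predict(x) == y)
        assert acc >= 0.95

    def test_training_determinism(self):
        x, y = _separable_features(n=60, d=8, seed=1)
        cfg = TrainConfig(epochs=5, batch_size=16, learning_rate=1e-3, seed=3)
        c1 = train_ann(x, y, ANNSpec(hidden_layers=(16,)), cfg)
        c2 = train_ann(x, y, ANNSpec(hidden_layers=(16,)), cfg)
        for p1, p2 in zip(c1.net.parameters(), c2.net.parameters()):
            np.testing.assert_array_equal(p1, p2)

    def test_loss_trend_decreasing_on_separable_toy(self):
        x, y = _separable_features(n=90, d=10, seed=2)
        clf = train_ann(x, y, ANNSpec(hidden_layers=(32,)),
                        TrainConfig(epochs=40, batch_size=16,
                                    learning_rate=1e-3, seed=0))
        hist = np.asarray(clf.loss_history)
        assert np.all(np.isfinite(hist))
        assert np.median(hist[20:]) < np.median(hist[:20])

    def test_divergence_reports_epoch(self):
        x, y = _separable_features(n=30, d=4, seed=3)
        x[0, 0] = np.inf  # propagates to a non-finite loss
        with pytest.raises(DivergenceError) as excinfo:
            train_ann(x, y, ANNSpec(hidden_layers=(8,)),
                      TrainConfig(epochs=3, batch_size=8,
                                  learning_rate=1e-3, seed=0))
        assert excinfo.value.epoch == 0


class TestCNN:
    def test_train_and_predict_shapes(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((12, 64, 4))
        y = np.array(["rest", "right", "left"] * 4)
        clf = train_cnn(x, y, CNNSpec(conv_filters=(4,)),
                        TrainConfig(epochs=2, batch_size=4,
                                    learning_rate=1e-3, seed=0))
        pred = predict(clf, x)
        assert pred.shape == (12,)
        probs = clf.predict_proba(x)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_repeated_prediction_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 32, 2))
        y = np.array(["rest", "right", "left"] * 2)
        clf = train_cnn(x, y, CNNSpec(conv_filters=(2,)),
                        TrainConfig(epochs=1, batch_size=4,
                                    learning_rate=1e-3, seed=0))
        np.testing.assert_array_equal(clf.predict_proba(x), clf.predict_proba(x))

    def test_training_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((9, 32, 2))
        y = np.array(["rest", "right", "left"] * 3)
        cfg = TrainConfig(epochs=3, batch_size=4, learning_rate=1e-3, seed=9)
        c1 = train_cnn(x, y, CNNSpec(conv_filters=(3,)), cfg)
        c2 = train_cnn(x, y, CNNSpec(conv_filters=(3,)), cfg)
        for p1, p2 in zip(c1.net.parameters(), c2.net.parameters()):
            np.testing.assert_array_equal(p1, p2)

    def test_input_shape_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((6, 32, 2))
        y = np.array(["rest", "right", "left"] * 2)
        clf = train_cnn(x, y, CNNSpec(conv_filters=(2,)),
                        TrainConfig(epochs=1, batch_size=4,
                                    learning_rate=1e-3, seed=0))
        with pytest.raises(ValueError, match="does not match"):
            clf.predict(rng.standard_normal((2, 32, 3)))


class TestSVM:
    def test_separable_clusters_perfect_training_accuracy(self):
        rng = np.random.default_rng(4)
        y = np.array(["rest", "right", "left"] * 20)
        x = rng.standard_normal((60, 5)) * 0.1
        x[:, 0] += np.select([y == "rest", y == "right", y == "left"],
                             [0.0, 8.0, -8.0])
        clf = train_svm(x, y, SVMSpec(c_regularization=10.0), seed=0)
        assert np.mean(clf.predict(x) == y) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            train_svm(np.zeros((5, 2)), ["rest"] * 5, SVMSpec())

    def test_increasing_c_never_hurts_training_accuracy(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((80, 4))
        y = np.where(x[:, 0] + 0.8 * rng.standard_normal(80) > 0, "right", "left")
        accs = []
        for c in [0.01, 0.1, 1.0, 10.0, 100.0]:
            clf = train_svm(x, y, SVMSpec(c_regularization=c), seed=0)
            accs.append(np.mean(clf.predict(x) == y))
        assert all(b >= a - 0.013 for a, b in zip(accs, accs[1:]))


class TestPCA:
    def test_points_on_line_first_component_explains_all(self):
        rng = np.random.default_rng(6)
        t = rng.standard_normal(50)
        x = np.outer(t, [1.0, 2.0])
        fitted = pca_fit(x, 2)
        assert fitted.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_mean_maps_to_zero(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((30, 5)) + 4.0
        fitted = pca_fit(x, 3)
        np.testing.assert_allclose(
            pca_transform(x.mean(axis=0, keepdims=True), fitted), 0.0, atol=1e-10)

    def test_reconstruction_error_decreases_with_components(self):
        """Eigendecomposition oracle: residual variance after k components
        equals the sum of the trailing eigenvalues, so it must decrease."""
        rng = np.random.default_rng(8)
        x = rng.standard_normal((40, 10)) @ np.diag(np.linspace(3, 0.1, 10))
        errors = []
        for k in (1, 3, 5, 8, 10):
            fitted = pca_fit(x, k)
            recon = fitted.inverse_transform(fitted.transform(x))
            errors.append(np.mean((x - recon) ** 2))
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))
        # oracle cross-check at k=3
        cov = np.cov(x.T, bias=False)
        eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        fitted = pca_fit(x, 3)
        np.testing.assert_allclose(
            np.sort(fitted.explained_variance_)[::-1], eigvals[:3], rtol=1e-8)

    def test_excessive_components_reduced_with_warning(self):
        x = np.random.default_rng(9).standard_normal((5, 3))
        with pytest.warns(UserWarning, match="reducing"):
            fitted = pca_fit(x, 10)
        assert fitted.n_components_ <= 3
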