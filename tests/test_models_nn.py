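"""Linear-activation networks: architecture laws, training, determinism."""

import numpy as np
import pytest

from mvpdkit.evaluate import variance_explained
from mvpdkit.models_linear import fit_ridge, predict
from mvpdkit.models_nn import (
    NNArchitectureSpec,
    TrainingConfig,
    _BN_EPS,
    build_network,
    layer_widths,
    n_affine_parameters,
    predict_network,
    sample_batch_schedule,
    train_network,
)


class TestArchitecture:
    def test_standard_parameter_count_formula(self):
        spec = NNArchitectureSpec("standard", 1, 100, 80, 64)
        assert n_affine_parameters(spec) == 80 * 100 + 100 + 100 * 64 + 64 == 14564
        # enumeration agrees with the formula
        net = build_network(spec, seed=0)
        counted = sum(w.size for w in net.weights) + sum(b.size for b in net.biases)
        assert counted == 14564

    def test_dense_width_law(self):
        spec = NNArchitectureSpec("dense", 2, 5, 10, 3)
        widths = layer_widths(spec)
        assert widths == [(10, 5), (15, 5), (20, 3)]
        # layer ℓ input width = input_dim + (ℓ-1)·hidden_units
        spec5 = NNArchitectureSpec("dense", 5, 100, 80, 64)
        for ell, (din, _) in enumerate(layer_widths(spec5)[:-1], start=1):
            assert din == 80 + (ell - 1) * 100
        assert layer_widths(spec5)[-1][0] == 80 + 5 * 100

    @pytest.mark.parametrize("kind,L,h,din,dout", [
        ("standard", 3, 7, 11, 5),
        ("dense", 3, 7, 11, 5),
        ("dense", 1, 4, 6, 2),
    ])
    def test_parameter_count_matches_enumeration(self, kind, L, h, din, dout):
        spec = NNArchitectureSpec(kind, L, h, din, dout)
        net = build_network(spec, seed=1)
        counted = sum(w.size for w in net.weights) + sum(b.size for b in net.biases)
        assert counted == n_affine_parameters(spec)

    def test_same_seed_gives_identical_initialization(self):
        spec = NNArchitectureSpec("dense", 2, 8, 5, 4)
        n1, n2 = build_network(spec, seed=9), build_network(spec, seed=9)
        for a, b in zip(n1.weights + n1.biases, n2.weights + n2.biases):
            np.testing.assert_array_equal(a, b)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NNArchitectureSpec("resnet", 1, 10, 5, 5)
        with pytest.raises(ValueError):
            NNArchitectureSpec("standard", 0, 10, 5, 5)


class TestBatchSchedule:
    def test_partitions_all_indices(self):
        batches = sample_batch_schedule(10, 4, epoch_seed=0)
        assert [len(b) for b in batches] == [4, 4, 2]
        assert sorted(np.concatenate(batches)) == list(range(10))

    def test_small_T_single_batch(self):
        batches = sample_batch_schedule(5, 32, epoch_seed=1)
        assert len(batches) == 1 and len(batches[0]) == 5

    def test_seed_determinism(self):
        a = sample_batch_schedule(50, 8, epoch_seed=7)
        b = sample_batch_schedule(50, 8, epoch_seed=7)
        c = sample_batch_schedule(50, 8, epoch_seed=8)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def _total_loss(net, xb, yb):
    """Objective the backward pass implements: squared error summed over
    output units, averaged over batch rows."""
    from mvpdkit.models_nn import _forward_train

    yhat, _ = _forward_train(net, xb)
    return float(((yhat - yb) ** 2).sum() / xb.shape[0])


class TestTraining:
    def test_zero_epochs_is_a_no_op(self, rng):
        spec = NNArchitectureSpec("standard", 1, 6, 4, 3)
        net = build_network(spec, seed=0)
        out = train_network(net, rng.normal(size=(4, 20)), rng.normal(size=(3, 20)),
                            TrainingConfig(epochs=0))
        for a, b in zip(net.weights + net.biases, out.weights + out.biases):
            np.testing.assert_array_equal(a, b)
        assert not out.trained

    def test_scalar_gain_recovers_factor_two(self, rng):
        X = rng.normal(size=(1, 300))
        Y = 2.0 * X
        spec = NNArchitectureSpec("standard", 1, 10, 1, 1)
        net = build_network(spec, seed=0)
        # full-batch training makes the normalization statistics exact, so
        # the composed end-to-end gain is identifiable to tight tolerance
        cfg = TrainingConfig(learning_rate=0.01, epochs=300, batch_size=300, seed=0)
        trained = train_network(net, X, Y, cfg)
        f0 = predict_network(trained, np.array([[0.0]]))[0, 0]
        f1 = predict_network(trained, np.array([[1.0]]))[0, 0]
        assert (f1 - f0) == pytest.approx(2.0, abs=0.05)

    def test_noiseless_linear_problem_training_loss_collapses(self, rng):
        B = rng.normal(size=(30, 20))
        X = rng.normal(size=(20, 800))
        Y = B @ X
        spec = NNArchitectureSpec("standard", 1, 100, 20, 30)
        net = build_network(spec, seed=0)
        # larger batches shrink the batch-statistics noise floor of the
        # normalization stage enough for the loss to collapse
        trained = train_network(net, X, Y,
                                TrainingConfig(epochs=300, batch_size=256, seed=0))
        assert trained.loss_history[-1] <= 0.02 * trained.loss_history[0]
        assert trained.loss_history[-1] < trained.loss_history[0]
        assert len(trained.loss_history) == 300

    @pytest.mark.parametrize("kind", ["standard", "dense"])
    def test_backward_pass_matches_finite_differences(self, rng, kind):
        """Analytic gradients (including through batch normalization) agree
        with central finite differences on every weight and bias."""
        from mvpdkit.models_nn import _backward, _forward_train

        spec = NNArchitectureSpec(kind, 2, 3, 4, 2)
        net = build_network(spec, seed=5)
        xb = rng.normal(size=(6, 4))
        yb = rng.normal(size=(6, 2))
        yhat, caches = _forward_train(net, xb)
        dout = 2.0 * (yhat - yb) / xb.shape[0]
        dW, db = _backward(net, caches, dout)
        eps = 1e-6
        for arrs, grads in ((net.weights, dW), (net.biases, db)):
            for arr, g in zip(arrs, grads):
                flat = arr.ravel()
                for idx in range(0, flat.size, max(1, flat.size // 5)):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = _total_loss(net, xb, yb)
                    flat[idx] = orig - eps
                    lm = _total_loss(net, xb, yb)
                    flat[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert g.ravel()[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_nonfinite_loss_aborts_with_guidance(self, rng):
        spec = NNArchitectureSpec("standard", 1, 10, 3, 2, batch_norm=False)
        net = build_network(spec, seed=0)
        X = rng.normal(size=(3, 100)) * 1e4
        Y = rng.normal(size=(2, 100)) * 1e4
        with pytest.raises(FloatingPointError, match="learning rate"):
            train_network(net, X, Y, TrainingConfig(learning_rate=10.0, epochs=5))

    def test_full_reproducibility(self, rng):
        X = rng.normal(size=(5, 120))
        Y = rng.normal(size=(4, 120))
        spec = NNArchitectureSpec("dense", 2, 8, 5, 4)
        cfg = TrainingConfig(epochs=5, seed=11)
        t1 = train_network(build_network(spec, seed=11), X, Y, cfg)
        t2 = train_network(build_network(spec, seed=11), X, Y, cfg)
        for a, b in zip(t1.weights + t1.biases, t2.weights + t2.biases):
            np.testing.assert_array_equal(a, b)
        assert t1.loss_history == t2.loss_history


class TestPrediction:
    def test_column_alone_equals_column_in_batch(self, rng):
        X = rng.normal(size=(4, 60))
        Y = rng.normal(size=(3, 60))
        spec = NNArchitectureSpec("dense", 2, 6, 4, 3)
        net = train_network(build_network(spec, seed=2), X, Y, TrainingConfig(epochs=3))
        X_test = rng.normal(size=(4, 10))
        full = predict_network(net, X_test)
        single = predict_network(net, X_test[:, 3:4])
        assert np.max(np.abs(full[:, 3:4] - single)) < 1e-6

    def test_zero_output_weights_yield_bias(self, rng):
        spec = NNArchitectureSpec("standard", 1, 5, 3, 2, batch_norm=False)
        net = build_network(spec, seed=0)
        net.weights[-1][:] = 0.0
        net.biases[-1][:] = [3.0, -1.0]
        out = predict_network(net, rng.normal(size=(3, 4)))
        np.testing.assert_array_equal(out, np.tile([[3.0], [-1.0]], 4))

    def test_untrained_batch_norm_statistics_rejected(self, rng):
        net = build_network(NNArchitectureSpec("standard", 1, 5, 3, 2), seed=0)
        with pytest.raises(RuntimeError, match="never.*trained|trained"):
            predict_network(net, rng.normal(size=(3, 4)))

    def test_predictions_equal_composed_affine_map(self, rng):
        """In eval mode the whole network is one affine map; composing the
        frozen normalization and the layer affines by hand reproduces the
        forward pass."""
        X = rng.normal(size=(4, 100))
        Y = rng.normal(size=(3, 100))
        spec = NNArchitectureSpec("standard", 2, 6, 4, 3)
        net = train_network(build_network(spec, seed=4), X, Y, TrainingConfig(epochs=4))
        A = np.eye(4)
        c = np.zeros(4)
        for i, (W, b) in enumerate(zip(net.weights, net.biases)):
            s = 1.0 / np.sqrt(net.bn_var[i] + _BN_EPS)
            # bn: x -> s*(x - m);  affine: W x + b
            A_bn = np.diag(s)
            c_bn = -net.bn_mean[i] * s
            A = W @ A_bn @ A
            c = W @ (A_bn @ c + c_bn) + b
        X_test = rng.normal(size=(4, 15))
        oracle = A @ X_test + c[:, None]
        np.testing.assert_allclose(predict_network(net, X_test), oracle, atol=1e-5)

    def test_training_varexpl_never_beats_ols(self, rng):
        """Expressivity ceiling: a linear-activation network cannot exceed
        the MSE-optimal linear map on its own training data."""
        B = rng.normal(size=(6, 5))
        X = rng.normal(size=(5, 400))
        Y = B @ X + rng.normal(scale=1.0, size=(6, 400))
        ols = fit_ridge(X, Y, strength=0.0)
        ols_ve = variance_explained(Y, predict(ols, X)).mean()
        spec = NNArchitectureSpec("standard", 1, 50, 5, 6)
        net = train_network(build_network(spec, seed=0), X, Y,
                            TrainingConfig(epochs=80, seed=0))
        nn_ve = variance_explained(Y, predict_network(net, X)).mean()
        assert nn_ve <= ols_ve + 0.01


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(3, 50))
        Y = rng.normal(size=(2, 50))
        spec = NNArchitectureSpec("dense", 2, 4, 3, 2)
        net = train_network(build_network(spec, seed=1), X, Y, TrainingConfig(epochs=2))
        net.save(tmp_path / "ckpt.npz")
        from mvpdkit.models_nn import NNArtifact

        loaded = NNArtifact.load(tmp_path / "ckpt.npz")
        X_test = rng.normal(size=(3, 7))
        np.testing.assert_array_equal(
            predict_network(net, X_test), predict_network(loaded, X_test)
        )
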