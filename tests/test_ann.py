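"""Linear network: affine equivalence, gradients, training dynamics."""

import numpy as np
import pytest

from specal.ann import (
    PRESETS,
    AnnModel,
    fit_scaler,
    _loss_and_grads,
    hidden_size_scan,
    init_ann,
    predict_ann,
    train_ann,
    train_preset,
)


@pytest.fixture()
def tiny_data():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(6, 4))
    Y = np.abs(rng.normal(size=(6, 2))) + 1.0
    return X, Y


class TestInit:
    def test_seed_determinism(self):
        a = init_ann(251, 4, 5, seed=9)
        b = init_ann(251, 4, 5, seed=9)
        assert np.array_equal(a.W1, b.W1) and np.array_equal(a.W2, b.W2)

    def test_layer_shapes_match_network_topology(self):
        m = init_ann(251, n_hidden=4, n_out=5, seed=0)
        assert m.W1.shape == (4, 251)
        assert m.W2.shape == (5, 4)
        assert np.all(m.b1 == 0) and np.all(m.b2 == 0)

    def test_zero_input_forward_is_output_bias(self):
        m = init_ann(10, 3, 2, seed=1)
        out = m.forward_scaled(np.zeros((1, 10)))
        assert np.allclose(out, m.W2 @ m.b1 + m.b2)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            init_ann(0, 4, 5)


class TestAffineEquivalence:
    def test_purelin_network_is_exactly_affine(self, tiny_data):
        X, Y = tiny_data
        model, _ = train_ann(init_ann(4, 3, 2, seed=2), X, Y, epochs=20, lr=0.05)
        Xs = model.scaler.scale_x(X)
        A, c = model.as_affine()
        layered = model.forward_scaled(Xs)
        composed = Xs @ A.T + c
        assert np.allclose(layered, composed, rtol=0, atol=1e-15 * max(1, np.abs(layered).max()))


class TestGradients:
    def test_gradient_matches_finite_differences(self, tiny_data):
        X, Y = tiny_data
        model = init_ann(4, 3, 2, seed=4)
        scaler = fit_scaler(X, Y)
        Xs, Ys = scaler.scale_x(X), scaler.scale_y(Y)
        loss0, (gW1, gb1, gW2, gb2) = _loss_and_grads(model, Xs, Ys)
        eps = 1e-6
        from dataclasses import replace

        for grad, attr in ((gW1, "W1"), (gb1, "b1"), (gW2, "W2"), (gb2, "b2")):
            arr = getattr(model, attr)
            it = np.nditer(arr, flags=["multi_index"])
            for _ in range(min(arr.size, 6)):
                idx = it.multi_index
                bumped = arr.copy()
                bumped[idx] += eps
                lp = _loss_and_grads(replace(model, **{attr: bumped}), Xs, Ys)[0]
                bumped[idx] -= 2 * eps
                lm = _loss_and_grads(replace(model, **{attr: bumped}), Xs, Ys)[0]
                fd = (lp - lm) / (2 * eps)
                assert grad[idx] == pytest.approx(fd, rel=1e-5, abs=1e-10)
                it.iternext()


class TestTraining:
    def test_zero_learning_rate_is_a_no_op(self, tiny_data):
        X, Y = tiny_data
        init = init_ann(4, 3, 2, seed=5)
        model, trace = train_ann(init, X, Y, epochs=10, lr=0.0)
        assert np.array_equal(model.W1, init.W1)
        assert np.allclose(trace, trace[0])

    def test_tiny_linear_system_converges_and_matches_gd_oracle(self):
        """Step-for-step agreement with an independently coded descent loop."""
        rng = np.random.default_rng(6)
        X = rng.normal(size=(4, 3))
        Y = X @ rng.normal(size=(3, 1)) + 5.0
        model = init_ann(3, 2, 1, seed=7)
        lr, epochs = 0.1, 4000
        trained, trace = train_ann(model, X, Y, epochs=epochs, lr=lr)
        assert trace[-1] < 1e-6

        # oracle: explicit descent on the scaled problem
        scaler = fit_scaler(X, Y)
        Xs, Ys = scaler.scale_x(X), scaler.scale_y(Y)
        W1, b1, W2, b2 = (model.W1.copy(), model.b1.copy(),
                          model.W2.copy(), model.b2.copy())
        n, m = Ys.shape
        for _ in range(epochs):
            H = Xs @ W1.T + b1
            E = H @ W2.T + b2 - Ys
            dY = 2.0 * E / (n * m)
            gW2, gb2 = dY.T @ H, dY.sum(0)
            dH = dY @ W2
            gW1, gb1 = dH.T @ Xs, dH.sum(0)
            W1, b1 = W1 - lr * gW1, b1 - lr * gb1
            W2, b2 = W2 - lr * gW2, b2 - lr * gb2
        assert np.allclose(trained.W1, W1, rtol=1e-12, atol=1e-14)
        assert np.allclose(trained.W2, W2, rtol=1e-12, atol=1e-14)

    def test_loss_non_increasing_at_small_rate(self, clean_calval):
        X, Y, _, _ = clean_calval
        model = init_ann(X.shape[1], 4, 5, seed=8)
        _, trace = train_ann(model, X, Y, epochs=200, lr=0.01)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_training_determinism_under_seed(self, clean_calval):
        X, Y, _, _ = clean_calval
        m1, t1 = train_preset(X, Y, preset="legacy", seed=3)
        m2, t2 = train_preset(X, Y, preset="legacy", seed=3)
        assert np.array_equal(m1.W1, m2.W1)
        assert np.array_equal(t1, t2)

    def test_divergence_raises_informative_error(self, tiny_data):
        X, Y = tiny_data
        model = init_ann(4, 3, 2, seed=9)
        with pytest.raises(FloatingPointError, match="scal"):
            train_ann(model, X, Y, epochs=500, lr=50.0)

    def test_trace_has_one_entry_per_epoch(self, tiny_data):
        X, Y = tiny_data
        _, trace = train_ann(init_ann(4, 3, 2, seed=1), X, Y, epochs=37, lr=0.01)
        assert len(trace) == 37


class TestPrediction:
    def test_untrained_model_refuses_to_predict(self):
        with pytest.raises(ValueError, match="untrained"):
            predict_ann(init_ann(4, 3, 2, seed=0), np.zeros((1, 4)))

    def test_dimension_mismatch(self, tiny_data):
        X, Y = tiny_data
        model, _ = train_ann(init_ann(4, 3, 2, seed=0), X, Y, epochs=5, lr=0.01)
        with pytest.raises(ValueError, match="columns"):
            predict_ann(model, np.zeros((1, 5)))

    def test_accuracy_preset_recovers_noiseless_design_data(self, clean_calval):
        """Converged full-width linear net is exact on clean linear spectra."""
        X, Y, X_val, Y_val = clean_calval
        model, trace = train_preset(X, Y, preset="accuracy", seed=0)
        rec = 100.0 * predict_ann(model, X_val) / Y_val
        assert np.abs(rec - 100.0).max() < 1.0

    def test_legacy_preset_configuration_is_faithful(self):
        cfg = PRESETS["legacy"]
        assert cfg["n_hidden"] == 4 and cfg["lr"] == 0.1 and cfg["epochs"] == 50


class TestHiddenScan:
    def test_reports_rmsec_per_width(self, clean_calval):
        X, Y, _, _ = clean_calval
        out = hidden_size_scan(X, Y, hidden_sizes=(1, 2), epochs=10, lr=0.05)
        assert set(out) == {1, 2}
        assert all(v >= 0 for v in out.values())
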