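import numpy as np
import pytest

from patchlead import preprocess
from patchlead.lstm import (LSTMCellWeights, LSTMLeadRegressor, LSTMSpec,
                            TwelveLeadLSTM, _init_weights, _layer_forward,
                            _net_backward, _net_forward, build_lead_model,
                            load_bundle, lstm_cell_forward, save_bundle,
                            stitch_predictions)
from patchlead.records import MultiLeadRecord, PATCH_LEADS, STANDARD_LEADS


class TestCell:
    def test_zero_weights_give_zero_state(self):
        w = LSTMCellWeights(np.zeros((3, 8)), np.zeros((2, 8)), np.zeros(8))
        h, c = lstm_cell_forward([1.0, -2.0, 0.5], np.zeros(2), np.zeros(2), w)
        np.testing.assert_allclose(h, 0.0)
        np.testing.assert_allclose(c, 0.0)

    def test_scalar_hand_worked_example(self):
        # all weights one, biases zero, x=1, zero initial state:
        # gates sigma(1)=0.7311, candidate tanh(1)=0.7616,
        # c = 0.7311*0.7616 = 0.5568, h = 0.7311*tanh(0.5568) = 0.3697
        w = LSTMCellWeights(np.ones((1, 4)), np.ones((1, 4)), np.zeros(4))
        h, c = lstm_cell_forward([1.0], [0.0], [0.0], w)
        assert c[0] == pytest.approx(0.5568, abs=1e-4)
        assert h[0] == pytest.approx(0.3697, abs=1e-4)

    def test_saturated_forget_open_input_closed_carries_memory(self):
        # forget bias +20 (F→1), input bias −20 (I→0): c_t = c_prev exactly
        b = np.array([-20.0, 20.0, 0.0, 0.0])
        w = LSTMCellWeights(np.zeros((1, 4)), np.zeros((1, 4)), b)
        c_prev = np.array([0.37])
        _, c = lstm_cell_forward([5.0], [0.1], c_prev, w)
        assert c[0] == pytest.approx(0.37, abs=1e-8)

    @pytest.mark.parametrize("trial", range(10))
    def test_vectorized_layer_matches_explicit_cell_steps(self, trial):
        """Library-style batched forward equals stepping Eqs. (2)-(7) by hand."""
        rng = np.random.default_rng(trial)
        H, D, T = 5, 3, 7
        cell = LSTMCellWeights(rng.normal(scale=0.5, size=(D, 4 * H)),
                               rng.normal(scale=0.5, size=(H, 4 * H)),
                               rng.normal(scale=0.5, size=4 * H))
        x = rng.normal(size=(2, T, D))
        h_vec, _ = _layer_forward(x, cell)
        for b in range(2):
            h_prev, c_prev = np.zeros(H), np.zeros(H)
            for t in range(T):
                h_prev, c_prev = lstm_cell_forward(x[b, t], h_prev, c_prev,
                                                   cell)
                np.testing.assert_allclose(h_vec[b, t], h_prev, atol=1e-5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LSTMCellWeights(np.zeros((3, 8)), np.zeros((2, 9)), np.zeros(8))


class TestGradients:
    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        layers, hw, hwx, hb = _init_weights(2, 4, 3, rng, np.float64)
        x = rng.normal(size=(2, 6, 3))
        y = rng.normal(size=(2, 6))

        def loss():
            yhat, _, _ = _net_forward(x, layers, hw, hwx, hb)
            return float(np.mean((yhat - y) ** 2))

        yhat, h_top, caches = _net_forward(x, layers, hw, hwx, hb)
        grads = _net_backward(2.0 * (yhat - y) / yhat.size, x, layers, hw,
                              h_top, caches)
        params = []
        for cell in layers:
            params += [cell.W, cell.U, cell.b]
        params += [hw, hwx, hb]
        rng2 = np.random.default_rng(1)
        for p, g in zip(params, grads):
            flat = p.reshape(-1)
            gflat = g.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(4, flat.size),
                                   replace=False):
                orig = flat[idx]
                flat[idx] = orig + 1e-6
                lp = loss()
                flat[idx] = orig - 1e-6
                lm = loss()
                flat[idx] = orig
                num = (lp - lm) / 2e-6
                assert num == pytest.approx(gflat[idx], rel=1e-3, abs=1e-7)


class TestBuildAndTrain:
    def test_same_seed_identical_initial_weights(self):
        spec = LSTMSpec(n_layers=2, hidden=6, epochs=1)
        a = build_lead_model(spec, seed=7)
        b = build_lead_model(spec, seed=7)
        for ca, cb in zip(a.layers_, b.layers_):
            np.testing.assert_array_equal(ca.W, cb.W)
            np.testing.assert_array_equal(ca.U, cb.U)
        c = build_lead_model(spec, seed=8)
        assert not np.array_equal(a.layers_[0].W, c.layers_[0].W)

    def test_forward_pass_shape_and_boundedness(self):
        model = build_lead_model(LSTMSpec(hidden=8, window=50), seed=0)
        win = np.random.default_rng(0).normal(size=(2, 3, 50))
        out = model._predict_windows(win)
        assert out.shape == (2, 50)
        assert np.all(np.isfinite(out))
        # zero input with zero head bias: |y| bounded by head weight norm
        # (hidden activations are within (-1, 1)) plus nothing from the skip
        zero = model._predict_windows(np.zeros((1, 3, 50)))
        assert np.max(np.abs(zero)) <= np.abs(model.head_w_).sum() + 1e-6

    def test_zero_epochs_is_noop(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(300, 3))
        y = rng.normal(size=300)
        model = LSTMLeadRegressor(n_layers=2, hidden=6, window=50, step=25,
                                  epochs=0, seed=3)
        model.fit(x, y)
        fresh = build_lead_model(
            LSTMSpec(n_layers=2, hidden=6, window=50), seed=3)
        for ca, cb in zip(model.layers_, fresh.layers_):
            np.testing.assert_array_equal(ca.W, cb.W)
        assert model.loss_history_ == []

    def test_overfits_small_window_set(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(300, 3))
        y = 0.7 * x[:, 0] - 0.4 * x[:, 1] + 0.2 * np.tanh(x[:, 2])
        model = LSTMLeadRegressor(n_layers=2, hidden=16, window=50, step=25,
                                  batch_size=10, epochs=300,
                                  learning_rate=0.01, seed=0)
        model.fit(x, y)  # 11 windows
        assert model.loss_history_[-1] < 0.01 * model.loss_history_[0]

    def test_learns_linear_map_and_generalizes(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(900, 3))
        y = 1.5 * x[:, 0] - 0.5 * x[:, 1] + 0.25 * x[:, 2] + 3.0
        model = LSTMLeadRegressor(n_layers=2, hidden=8, window=50, step=10,
                                  batch_size=20, epochs=60,
                                  learning_rate=0.01, seed=0, predict_step=5)
        model.fit(x[:600], y[:600])
        assert model.loss_history_[-1] < model.loss_history_[0]
        yhat = model.predict(x[600:])
        r = np.corrcoef(yhat, y[600:])[0, 1]
        assert r > 0.95

    def test_training_determinism(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(300, 3))
        y = rng.normal(size=300)
        kwargs = dict(n_layers=2, hidden=6, window=50, step=10, batch_size=8,
                      epochs=3, seed=12)
        a = LSTMLeadRegressor(**kwargs).fit(x, y)
        b = LSTMLeadRegressor(**kwargs).fit(x, y)
        np.testing.assert_allclose(a.loss_history_, b.loss_history_,
                                   rtol=1e-6)
        np.testing.assert_array_equal(a.layers_[0].W, b.layers_[0].W)

    def test_nan_loss_aborts_with_diagnostic(self):
        model = LSTMLeadRegressor(n_layers=1, hidden=4, window=10, step=5,
                                  epochs=2, seed=0)
        model._build(3)
        model.x_norm_ = preprocess.ChannelNormalizer().fit(np.zeros((10, 3)))
        model.y_norm_ = preprocess.ChannelNormalizer().fit(np.zeros(10))
        bad = preprocess.WindowDataset(
            inputs=np.full((4, 3, 10), np.nan), targets=np.zeros((4, 10)),
            window=10, step=5)
        with pytest.raises(RuntimeError, match="non-finite"):
            model._train(bad, np.random.default_rng(0))


class TestStitching:
    def test_zero_predictions_give_zero_signal(self):
        out = stitch_predictions(np.zeros((5, 10)), np.arange(5), 14)
        np.testing.assert_array_equal(out, np.zeros(14))

    def test_constant_predictions_average_to_constant(self):
        out = stitch_predictions(np.full((6, 10), 3.25), np.arange(6), 15)
        np.testing.assert_allclose(out, 3.25)

    def test_window_index_predictions_match_enumeration_oracle(self):
        # window k predicts value k everywhere; sample n must equal the
        # mean of k over windows covering n, enumerated directly
        window, n = 10, 25
        starts = np.arange(n - window + 1)
        preds = np.tile(starts[:, None].astype(float), (1, window))
        out = stitch_predictions(preds, starts, n)
        for sample in range(n):
            covering = [k for k in starts
                        if k <= sample < k + window]
            assert out[sample] == pytest.approx(np.mean(covering))

    def test_uncovered_sample_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            stitch_predictions(np.zeros((1, 5)), np.array([0]), 10)

    def test_too_short_input_rejected(self):
        model = LSTMLeadRegressor(window=250)
        model._build(3)
        model.x_norm_ = preprocess.ChannelNormalizer().fit(np.zeros((10, 3)))
        model.y_norm_ = preprocess.ChannelNormalizer().fit(np.zeros(10))
        with pytest.raises(ValueError, match="shorter"):
            model.predict(np.zeros((100, 3)))


@pytest.fixture(scope="module")
def tiny_bundle():
    rng = np.random.default_rng(0)
    patch = MultiLeadRecord(lead_names=PATCH_LEADS, fs=250.0,
                            data=rng.normal(size=(300, 3)))
    target = MultiLeadRecord(lead_names=STANDARD_LEADS, fs=250.0,
                             data=rng.normal(size=(300, 12)))
    bundle = TwelveLeadLSTM(n_layers=1, hidden=4, window=50, step=50,
                            epochs=1, seed=5, predict_step=10)
    bundle.fit(patch, target)
    return bundle, patch


class TestTwelveLeadBundle:

    def test_reconstruction_stacks_single_lead_calls(self, tiny_bundle):
        bundle, patch = tiny_bundle
        rec = bundle.reconstruct(patch)
        assert rec.lead_names == STANDARD_LEADS
        assert rec.n_samples == patch.n_samples
        for name in ("I", "V3", "V6"):
            np.testing.assert_array_equal(
                rec.lead(name), bundle.models_[name].predict(patch.data))

    def test_missing_lead_model_error_names_lead(self, tiny_bundle):
        bundle, patch = tiny_bundle
        partial = TwelveLeadLSTM()
        partial.models_ = {k: v for k, v in bundle.models_.items()
                           if k != "V4"}
        with pytest.raises(ValueError, match="V4"):
            partial.reconstruct(patch)

    def test_bundle_serialization_round_trip(self, tiny_bundle, tmp_path):
        bundle, patch = tiny_bundle
        path = tmp_path / "bundle.npz"
        save_bundle(bundle, path)
        back = load_bundle(path)
        orig = bundle.reconstruct(patch)
        loaded = back.reconstruct(patch)
        np.testing.assert_allclose(loaded.data, orig.data, atol=1e-6)
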