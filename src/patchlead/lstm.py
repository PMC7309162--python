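"""Per-lead LSTM sequence regressors mapping 3×window patch segments to
one reconstructed target-lead segment.

The network is the classic Hochreiter–Schmidhuber cell, stacked three deep
with 50 hidden units by default, followed by a per-timestep linear head.
Training minimizes the mean squared reconstruction error over 1-s sliding
windows with Adam.  Everything — forward pass, backpropagation through time
and the optimizer — is implemented here in numpy: the model is small enough
that a desk CPU trains it, and an explicit implementation keeps the cell
arithmetic open to direct verification against hand-evaluated steps.

Gate layout in the fused weight matrices is ``[input, forget, candidate,
output]``: for layer input ``x_t`` and previous state ``(h, c)``,

    i = σ(x_t W_i + h U_i + b_i)        f = σ(x_t W_f + h U_f + b_f)
    g = tanh(x_t W_g + h U_g + b_g)     o = σ(x_t W_o + h U_o + b_o)
    c_t = f ⊙ c + i ⊙ g                 h_t = o ⊙ tanh(c_t)
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .preprocess import ChannelNormalizer, WindowDataset, make_windows
from .records import MultiLeadRecord, STANDARD_LEADS


@dataclass
class LSTMSpec:
    """Training hyperparameters; the defaults are the full-scale protocol
    (3 layers × 50 units, 1-s windows slid 1 sample, Adam 1e-3, batch 50,
    500 epochs)."""

    n_layers: int = 3
    hidden: int = 50
    window: int = 250
    step: int = 1
    batch: int = 50
    epochs: int = 500
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        for name in ("n_layers", "hidden", "window", "step", "batch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("epochs must be ≥ 0 and learning_rate > 0")


@dataclass
class LSTMCellWeights:
    """Fused weights of one cell: W (n_inputs, 4H), U (H, 4H), b (4H,)."""

    W: np.ndarray
    U: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.W = np.asarray(self.W)
        self.U = np.asarray(self.U)
        self.b = np.asarray(self.b)
        H = self.U.shape[0]
        if self.U.shape != (H, 4 * H) or self.W.shape[1] != 4 * H or \
                self.b.shape != (4 * H,):
            raise ValueError("inconsistent cell weight shapes")

    @property
    def hidden(self) -> int:
        return self.U.shape[0]


def lstm_cell_forward(x_t, h_prev, c_prev, weights: LSTMCellWeights):
    """One explicit cell step; returns ``(h_t, c_t)``.

    Inputs are (..., n_inputs) / (..., H) arrays.  This is the reference
    form the vectorized training path is tested against.
    """
    x_t = np.atleast_1d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_1d(np.asarray(c_prev, dtype=float))
    H = weights.hidden
    z = x_t @ weights.W + h_prev @ weights.U + weights.b
    i = expit(z[..., :H])
    f = expit(z[..., H:2 * H])
    g = np.tanh(z[..., 2 * H:3 * H])
    o = expit(z[..., 3 * H:])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


# --------------------------------------------------------------------------
# vectorized stacked network

def _init_weights(n_layers, hidden, n_inputs, rng, dtype):
    """Seeded uniform fan-in init; forget-gate bias raised to +1."""
    layers = []
    d = n_inputs
    for _ in range(n_layers):
        k = 1.0 / np.sqrt(hidden)
        W = rng.uniform(-k, k, size=(d, 4 * hidden))
        U = rng.uniform(-k, k, size=(hidden, 4 * hidden))
        b = rng.uniform(-k, k, size=4 * hidden)
        b[hidden:2 * hidden] += 1.0
        layers.append(LSTMCellWeights(W.astype(dtype), U.astype(dtype),
                                      b.astype(dtype)))
        d = hidden
    k = 1.0 / np.sqrt(hidden)
    head_w = rng.uniform(-k, k, size=hidden).astype(dtype)
    # direct input->output path: the output stage combines the three patch
    # channels with the recurrent state, so a (near-)linear lead map is
    # exactly representable and generalizes to unseen beat morphologies
    head_wx = np.zeros(n_inputs, dtype=dtype)
    head_b = np.zeros(1, dtype=dtype)
    return layers, head_w, head_wx, head_b


def _layer_forward(x, cell):
    """Run one LSTM layer over (B, T, D) input; returns h and a cache."""
    B, T, D = x.shape
    H = cell.hidden
    dtype = x.dtype
    # the input projection for every timestep in one BLAS call
    zx = x.reshape(B * T, D) @ cell.W
    zx = zx.reshape(B, T, 4 * H) + cell.b
    h = np.empty((B, T, H), dtype=dtype)
    c = np.empty((B, T, H), dtype=dtype)
    tc = np.empty((B, T, H), dtype=dtype)
    gates = np.empty((B, T, 4 * H), dtype=dtype)
    h_prev = np.zeros((B, H), dtype=dtype)
    c_prev = np.zeros((B, H), dtype=dtype)
    for t in range(T):
        z = zx[:, t] + h_prev @ cell.U
        i = expit(z[:, :H])
        f = expit(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = expit(z[:, 3 * H:])
        c_t = f * c_prev + i * g
        tc_t = np.tanh(c_t)
        h_t = o * tc_t
        gates[:, t, :H] = i
        gates[:, t, H:2 * H] = f
        gates[:, t, 2 * H:3 * H] = g
        gates[:, t, 3 * H:] = o
        c[:, t] = c_t
        tc[:, t] = tc_t
        h[:, t] = h_t
        h_prev, c_prev = h_t, c_t
    return h, (x, gates, c, tc, h)


def _layer_backward(dh_out, cell, cache):
    """BPTT through one layer.  ``dh_out`` is ∂L/∂h for every timestep.

    Returns (dx, dW, dU, db)."""
    x, gates, c, tc, h = cache
    B, T, D = x.shape
    H = cell.hidden
    dtype = x.dtype
    dz = np.empty((B, T, 4 * H), dtype=dtype)
    dh_next = np.zeros((B, H), dtype=dtype)
    dc_next = np.zeros((B, H), dtype=dtype)
    Ut = cell.U.T
    for t in range(T - 1, -1, -1):
        i = gates[:, t, :H]
        f = gates[:, t, H:2 * H]
        g = gates[:, t, 2 * H:3 * H]
        o = gates[:, t, 3 * H:]
        tc_t = tc[:, t]
        c_prev = c[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
        dh = dh_out[:, t] + dh_next
        do = dh * tc_t
        dct = dh * o * (1.0 - tc_t * tc_t) + dc_next
        dc_next = dct * f
        dz_t = dz[:, t]
        dz_t[:, :H] = dct * g * i * (1.0 - i)
        dz_t[:, H:2 * H] = dct * c_prev * f * (1.0 - f)
        dz_t[:, 2 * H:3 * H] = dct * i * (1.0 - g * g)
        dz_t[:, 3 * H:] = do * o * (1.0 - o)
        dh_next = dz_t @ Ut
    dz2 = dz.reshape(B * T, 4 * H)
    dW = x.reshape(B * T, D).T @ dz2
    h_shift = np.concatenate(
        [np.zeros((B, 1, H), dtype=dtype), h[:, :-1]], axis=1)
    dU = h_shift.reshape(B * T, H).T @ dz2
    db = dz2.sum(axis=0)
    dx = (dz2 @ cell.W.T).reshape(B, T, D)
    return dx, dW, dU, db


def _net_forward(x, layers, head_w, head_wx, head_b):
    caches = []
    h = x
    for cell in layers:
        h, cache = _layer_forward(h, cell)
        caches.append(cache)
    yhat = h @ head_w + x @ head_wx + head_b[0]
    return yhat, h, caches


def _net_backward(dyhat, x, layers, head_w, h_top, caches):
    """Returns gradients in the flat parameter order used by Adam."""
    B, T = dyhat.shape
    d_head_w = np.einsum("bth,bt->h", h_top, dyhat)
    d_head_wx = np.einsum("btd,bt->d", x, dyhat)
    d_head_b = np.array([dyhat.sum()], dtype=h_top.dtype)
    dh = dyhat[:, :, None] * head_w[None, None, :]
    grads = []
    for cell, cache in zip(reversed(layers), reversed(caches)):
        dh, dW, dU, db = _layer_backward(dh, cell, cache)
        grads.append((dW, dU, db))
    grads.reverse()
    flat = []
    for dW, dU, db in grads:
        flat.extend([dW, dU, db])
    flat.extend([d_head_w, d_head_wx, d_head_b])
    return flat


class _Adam:
    """Plain Adam with bias correction."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


# --------------------------------------------------------------------------
# estimator

class LSTMLeadRegressor(RegressorMixin, BaseEstimator):
    """Sequence regressor for one target lead.

    ``fit(X, y)`` takes the continuous training signals — ``X`` of shape
    (n_samples, n_channels) patch μV, ``y`` (n_samples,) target-lead μV —
    normalizes per channel, cuts sliding windows and trains.  ``predict(X)``
    reconstructs a full-length signal by averaging the predictions of all
    windows covering each sample and undoing the normalization.

    Parameters mirror :class:`LSTMSpec`; ``predict_step`` controls the
    stride of reconstruction windows (predictions are averaged, so larger
    strides trade a little smoothing for speed).
    """

    def __init__(self, n_layers=3, hidden=50, window=250, step=1,
                 batch_size=50, epochs=500, learning_rate=1e-3, seed=0,
                 shuffle=True, predict_step=1, dtype="float32"):
        self.n_layers = n_layers
        self.hidden = hidden
        self.window = window
        self.step = step
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.shuffle = shuffle
        self.predict_step = predict_step
        self.dtype = dtype

    # -- construction -----------------------------------------------------
    def _build(self, n_channels):
        rng = np.random.default_rng(self.seed)
        self.layers_, self.head_w_, self.head_wx_, self.head_b_ = \
            _init_weights(self.n_layers, self.hidden, n_channels, rng,
                          np.dtype(self.dtype))
        self.n_features_in_ = n_channels
        self.loss_history_ = []
        return rng

    def _params(self):
        flat = []
        for cell in self.layers_:
            flat.extend([cell.W, cell.U, cell.b])
        flat.extend([self.head_w_, self.head_wx_, self.head_b_])
        return flat

    # -- training ---------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_channels)")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        rng = self._build(X.shape[1])
        self.x_norm_ = ChannelNormalizer().fit(X)
        self.y_norm_ = ChannelNormalizer().fit(y)
        ds = make_windows(self.x_norm_.transform(X),
                          self.y_norm_.transform(y),
                          window=self.window, step=self.step)
        self._train(ds, rng)
        return self

    def _train(self, ds: WindowDataset, rng):
        dtype = np.dtype(self.dtype)
        # windows are (n, channels, window); the net runs time-major (B, T, D)
        inputs = np.ascontiguousarray(
            np.transpose(ds.inputs, (0, 2, 1)), dtype=dtype)
        targets = ds.targets.astype(dtype)
        n = inputs.shape[0]
        opt = _Adam(self._params(), self.learning_rate)
        for _ in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = inputs[idx]
                yb = targets[idx]
                yhat, h_top, caches = _net_forward(
                    xb, self.layers_, self.head_w_, self.head_wx_,
                    self.head_b_)
                err = yhat - yb
                loss = float(np.mean(err * err))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        "training diverged: non-finite loss "
                        f"(epoch {len(self.loss_history_)})")
                dyhat = (2.0 / err.size) * err
                grads = _net_backward(dyhat, xb, self.layers_, self.head_w_,
                                      h_top, caches)
                opt.step(grads)
                total += loss * len(idx)
            self.loss_history_.append(total / n)
        return self

    # -- reconstruction ---------------------------------------------------
    def _predict_windows(self, windows):
        """Normalized-domain forward pass over (n, n_ch, window) windows."""
        dtype = np.dtype(self.dtype)
        out = np.empty((windows.shape[0], windows.shape[2]), dtype=dtype)
        chunk = 64
        for s in range(0, windows.shape[0], chunk):
            xb = np.transpose(windows[s:s + chunk], (0, 2, 1)).astype(dtype)
            yhat, _, _ = _net_forward(xb, self.layers_, self.head_w_,
                                      self.head_wx_, self.head_b_)
            out[s:s + chunk] = yhat
        return out

    def predict(self, X):
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < self.window:
            raise ValueError(f"input length {n} shorter than window "
                             f"{self.window}")
        z = self.x_norm_.transform(X)
        starts = list(range(0, n - self.window + 1, self.predict_step))
        if starts[-1] != n - self.window:
            starts.append(n - self.window)
        starts = np.asarray(starts)
        idx = starts[:, None] + np.arange(self.window)[None, :]
        windows = np.transpose(z[idx], (0, 2, 1))  # (k, n_ch, window)
        preds = self._predict_windows(windows)
        stitched = stitch_predictions(preds.astype(float), starts, n)
        return self.y_norm_.inverse_transform(stitched)


def stitch_predictions(preds: np.ndarray, starts: np.ndarray,
                       n_samples: int) -> np.ndarray:
    """Average overlapping window predictions into one signal.

    ``preds`` is (n_windows, window); window k covers samples
    ``[starts[k], starts[k] + window)``.  Every output sample is the
    unweighted mean of all predictions covering it.
    """
    preds = np.asarray(preds, dtype=float)
    starts = np.asarray(starts, dtype=int)
    window = preds.shape[1]
    acc = np.zeros(n_samples)
    cnt = np.zeros(n_samples)
    for k, s in enumerate(starts):
        acc[s:s + window] += preds[k]
        cnt[s:s + window] += 1.0
    if np.any(cnt == 0):
        raise ValueError("windows do not cover every sample")
    return acc / cnt


# --------------------------------------------------------------------------
# spec-level operations

def build_lead_model(spec: LSTMSpec, seed=None,
                     n_channels: int = 3) -> LSTMLeadRegressor:
    """Construct an initialized (untrained) per-lead model."""
    model = LSTMLeadRegressor(
        n_layers=spec.n_layers, hidden=spec.hidden, window=spec.window,
        step=spec.step, batch_size=spec.batch, epochs=spec.epochs,
        learning_rate=spec.learning_rate,
        seed=spec.seed if seed is None else seed)
    model._build(n_channels)
    return model


def train_lead_model(model: LSTMLeadRegressor, dataset: WindowDataset,
                     epochs=None):
    """Train a built model on an already-windowed (normalized) dataset."""
    check_is_fitted(model, "layers_")
    if dataset.n_windows == 0:
        raise ValueError("empty window dataset")
    if epochs is not None:
        model.epochs = epochs
    rng = np.random.default_rng(model.seed + 1)
    model._train(dataset, rng)
    return model


def reconstruct_lead(model: LSTMLeadRegressor,
                     patch: MultiLeadRecord) -> np.ndarray:
    """Reconstruct one target-lead signal (μV) from a patch record."""
    return model.predict(patch.data)


class TwelveLeadLSTM:
    """Bundle of 12 independent per-lead LSTM regressors.

    ``fit`` trains one network per standard lead on a paired training
    segment; per-lead seeds are derived from the bundle seed so the whole
    bundle is reproducible.
    """

    def __init__(self, lead_names=STANDARD_LEADS, **params):
        self.lead_names = tuple(lead_names)
        self.params = params
        self.models_ = {}

    def fit(self, patch: MultiLeadRecord, target: MultiLeadRecord):
        base_seed = int(self.params.get("seed", 0))
        for j, name in enumerate(self.lead_names):
            p = dict(self.params)
            p["seed"] = (base_seed * 131 + j) % (2 ** 31)
            model = LSTMLeadRegressor(**p)
            model.fit(patch.data, target.lead(name))
            self.models_[name] = model
        return self

    def reconstruct(self, patch: MultiLeadRecord) -> MultiLeadRecord:
        missing = [n for n in self.lead_names if n not in self.models_]
        if missing:
            raise ValueError(f"missing trained model for lead(s): "
                             f"{', '.join(missing)}")
        cols = [self.models_[n].predict(patch.data) for n in self.lead_names]
        return MultiLeadRecord(lead_names=self.lead_names, fs=patch.fs,
                               data=np.column_stack(cols),
                               subject=patch.subject)


def reconstruct_12lead(models: TwelveLeadLSTM,
                       patch: MultiLeadRecord) -> MultiLeadRecord:
    return models.reconstruct(patch)


# --------------------------------------------------------------------------
# serialization

def save_bundle(bundle: TwelveLeadLSTM, path) -> None:
    """Serialize a trained bundle (weights + spec + normalization) to .npz."""
    arrays = {}
    meta = {"schema": "patchlead.lstm.v1", "leads": list(bundle.lead_names),
            "params": {}}
    for name, model in bundle.models_.items():
        meta["params"][name] = model.get_params()
        for li, cell in enumerate(model.layers_):
            arrays[f"{name}/W{li}"] = cell.W
            arrays[f"{name}/U{li}"] = cell.U
            arrays[f"{name}/b{li}"] = cell.b
        arrays[f"{name}/head_w"] = model.head_w_
        arrays[f"{name}/head_wx"] = model.head_wx_
        arrays[f"{name}/head_b"] = model.head_b_
        arrays[f"{name}/x_mean"] = model.x_norm_.mean_
        arrays[f"{name}/x_scale"] = model.x_norm_.scale_
        arrays[f"{name}/y_mean"] = np.atleast_1d(model.y_norm_.mean_)
        arrays[f"{name}/y_scale"] = np.atleast_1d(model.y_norm_.scale_)
        arrays[f"{name}/loss"] = np.asarray(model.loss_history_)
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_bundle(path) -> TwelveLeadLSTM:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        bundle = TwelveLeadLSTM(lead_names=meta["leads"])
        for name in meta["leads"]:
            model = LSTMLeadRegressor(**meta["params"][name])
            model.layers_ = []
            li = 0
            while f"{name}/W{li}" in data:
                model.layers_.append(LSTMCellWeights(
                    data[f"{name}/W{li}"], data[f"{name}/U{li}"],
                    data[f"{name}/b{li}"]))
                li += 1
            model.head_w_ = data[f"{name}/head_w"]
            model.head_wx_ = data[f"{name}/head_wx"]
            model.head_b_ = data[f"{name}/head_b"]
            model.n_features_in_ = model.layers_[0].W.shape[0]
            model.x_norm_ = ChannelNormalizer()
            model.x_norm_.mean_ = data[f"{name}/x_mean"]
            model.x_norm_.scale_ = data[f"{name}/x_scale"]
            model.y_norm_ = ChannelNormalizer()
            model.y_norm_.mean_ = float(data[f"{name}/y_mean"][0])
            model.y_norm_.scale_ = float(data[f"{name}/y_scale"][0])
            model.loss_history_ = list(data[f"{name}/loss"])
            bundle.models_[name] = model
    return bundle
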