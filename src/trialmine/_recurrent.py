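"""A small stacked-LSTM regressor in numpy (full-batch Adam, MSE loss).

The input is a fixed-length sequence of feature vectors per sample; the
last hidden state of the top layer feeds a linear readout producing one
scalar.  Targets are z-scored internally for optimization stability and
predictions are transformed back (and optionally clipped) by the caller.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from .errors import TrainingError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))


class _LSTMLayer:
    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(input_dim + hidden)
        self.Wx = rng.normal(0, scale, (input_dim, 4 * hidden))
        self.Wh = rng.normal(0, scale, (hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.hidden = hidden

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        """X: (N, T, D) -> hidden states (N, T, H) plus cache for backprop."""
        N, T, _ = X.shape
        H = self.hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        hs = np.zeros((N, T, H))
        cache = {"X": X, "i": [], "f": [], "o": [], "g": [], "c": [], "h_prev": [],
                 "c_prev": []}
        for t in range(T):
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            o = _sigmoid(z[:, 2 * H : 3 * H])
            g = np.tanh(z[:, 3 * H :])
            cache["h_prev"].append(h)
            cache["c_prev"].append(c)
            c = f * c + i * g
            h = o * np.tanh(c)
            for k, v in zip(("i", "f", "o", "g", "c"), (i, f, o, g, c)):
                cache[k].append(v)
            hs[:, t] = h
        return hs, cache

    def backward(
        self, d_hs: np.ndarray, cache: dict
    ) -> tuple[np.ndarray, list[np.ndarray]]:
        """d_hs: gradient wrt hidden states (N, T, H); returns dX and grads."""
        X = cache["X"]
        N, T, D = X.shape
        H = self.hidden
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_next = np.zeros((N, H))
        dc_next = np.zeros((N, H))
        for t in range(T - 1, -1, -1):
            i, f, o, g, c = (cache[k][t] for k in ("i", "f", "o", "g", "c"))
            h_prev, c_prev = cache["h_prev"][t], cache["c_prev"][t]
            dh = d_hs[:, t] + dh_next
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    do * o * (1 - o),
                    dg * (1 - g**2),
                ],
                axis=1,
            )
            dWx += X[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
        return dX, [dWx, dWh, db]


class LSTMRegressor:
    """Stacked LSTM layers with a scalar linear readout."""

    def __init__(
        self,
        layer_sizes: tuple[int, ...] = (16,),
        epochs: int = 300,
        learning_rate: float = 0.01,
        seed: int = 0,
    ):
        if not layer_sizes:
            raise TrainingError("need at least one recurrent layer")
        self.layer_sizes = tuple(layer_sizes)
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self._layers: list[_LSTMLayer] = []
        self._w_out: np.ndarray | None = None
        self._b_out = 0.0
        self._y_mean = 0.0
        self._y_std = 1.0
        self._constant: float | None = None

    def _forward(self, X: np.ndarray):
        caches = []
        h = X
        for layer in self._layers:
            h, cache = layer.forward(h)
            caches.append(cache)
        last = h[:, -1]
        pred = last @ self._w_out + self._b_out
        return pred, last, caches

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMRegressor":
        if X.ndim != 3 or len(X) == 0:
            raise TrainingError("X must be a non-empty (N, T, D) array")
        y = np.asarray(y, dtype=float)
        self._y_mean = float(y.mean())
        self._y_std = float(y.std())
        if self._y_std < 1e-9:  # degenerate target: constant predictor
            self._constant = self._y_mean
            return self
        yz = (y - self._y_mean) / self._y_std

        rng = np.random.default_rng(self.seed)
        self._layers = []
        in_dim = X.shape[2]
        for hidden in self.layer_sizes:
            self._layers.append(_LSTMLayer(in_dim, hidden, rng))
            in_dim = hidden
        self._w_out = rng.normal(0, 1.0 / np.sqrt(in_dim), in_dim)
        self._b_out = 0.0

        params: list[np.ndarray] = []
        for layer in self._layers:
            params.extend(layer.params())
        b_out_arr = np.array([self._b_out])
        params.append(self._w_out)
        params.append(b_out_arr)
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        N = len(X)
        for step in range(1, self.epochs + 1):
            pred, last, caches = self._forward(X)
            pred = last @ self._w_out + b_out_arr[0]
            err = pred - yz
            d_pred = 2.0 * err / N
            d_wout = last.T @ d_pred
            d_bout = np.array([d_pred.sum()])
            d_last = np.outer(d_pred, self._w_out)

            grads: list[np.ndarray] = []
            d_hs = np.zeros((N, X.shape[1], self._layers[-1].hidden))
            d_hs[:, -1] = d_last
            layer_grads: list[list[np.ndarray]] = []
            for layer, cache in zip(reversed(self._layers), reversed(caches)):
                d_hs, g = layer.backward(d_hs, cache)
                layer_grads.append(g)
            for g in reversed(layer_grads):
                grads.extend(g)
            grads.append(d_wout)
            grads.append(d_bout)

            for p, gr, mi, vi in zip(params, grads, m, v):
                np.clip(gr, -5.0, 5.0, out=gr)
                mi *= beta1
                mi += (1 - beta1) * gr
                vi *= beta2
                vi += (1 - beta2) * gr**2
                mhat = mi / (1 - beta1**step)
                vhat = vi / (1 - beta2**step)
                p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
        self._b_out = float(b_out_arr[0])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._constant is not None:
            return np.full(len(X), self._constant)
        if self._w_out is None:
            raise TrainingError("model is not fitted")
        pred, _, _ = self._forward(X)
        return pred * self._y_std + self._y_mean
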