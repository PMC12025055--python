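"""A compact NumPy LSTM binary classifier.

Single LSTM layer → dropout → dense(1, sigmoid), trained with binary
cross-entropy and RMSProp. Backpropagation through time is implemented
directly; for feature-vector input (one timestep) this reduces to a gated
feed-forward network and trains in well under a second at the sizes used
here. The implementation is deliberately small: one hidden layer, no
peepholes, no gradient clipping beyond a norm cap.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError

__all__ = ["NumpyLSTM"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class NumpyLSTM:
    """LSTM(units) → dropout → dense(1, sigmoid), RMSProp + BCE.

    Parameters mirror the usual recurrent-layer hyperparameters: ``units``
    (hidden size), ``dropout`` (rate on the final hidden state during
    training), ``epochs``, ``batch_size`` and the RMSProp ``learning_rate``
    (decay 0.9, epsilon 1e-7). The forget-gate bias starts at 1, the common
    initialisation that eases gradient flow early in training.
    """

    def __init__(
        self,
        n_features: int,
        units: int = 50,
        dropout: float = 0.1,
        epochs: int = 50,
        batch_size: int = 72,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ):
        if units < 1 or n_features < 1:
            raise ParameterError("units and n_features must be positive")
        if not 0.0 <= dropout < 1.0:
            raise ParameterError("dropout must lie in [0, 1)")
        self.n_features = n_features
        self.units = units
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = learning_rate
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._init_params()

    def _init_params(self) -> None:
        u, f = self.units, self.n_features
        rng = self._rng
        limit = np.sqrt(6.0 / (f + 4 * u))
        self.W = rng.uniform(-limit, limit, size=(f, 4 * u))
        # orthogonal recurrent kernel, block per gate
        blocks = []
        for _ in range(4):
            a = rng.standard_normal((u, u))
            q, r = np.linalg.qr(a)
            blocks.append(q * np.sign(np.diag(r)))
        self.U = np.concatenate(blocks, axis=1)
        self.b = np.zeros(4 * u)
        self.b[u : 2 * u] = 1.0  # forget-gate bias
        limit_d = np.sqrt(6.0 / (u + 1))
        self.Wd = rng.uniform(-limit_d, limit_d, size=(u, 1))
        self.bd = np.zeros(1)
        self._cache = {k: np.zeros_like(getattr(self, k)) for k in ("W", "U", "b", "Wd", "bd")}

    # ------------------------------------------------------------------
    def _forward(self, X: np.ndarray):
        """Run the recurrence; X is (batch, T, features)."""
        bsz, T, _ = X.shape
        u = self.units
        h = np.zeros((bsz, u))
        c = np.zeros((bsz, u))
        trace = []
        for t in range(T):
            z = X[:, t, :] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c + i * g
            tanh_c = np.tanh(c)
            h_prev = h
            h = o * tanh_c
            trace.append((i, f, g, o, c_prev, tanh_c, h_prev))
        return h, c, trace

    def _bptt(self, X: np.ndarray, y: np.ndarray, drop_mask: np.ndarray):
        bsz, T, _ = X.shape
        u = self.units
        h_T, _, trace = self._forward(X)
        h_drop = h_T * drop_mask
        logits = (h_drop @ self.Wd + self.bd).ravel()
        p = _sigmoid(logits)
        # BCE gradient wrt logits
        dlogit = (p - y)[:, None] / bsz
        grads = {
            "Wd": h_drop.T @ dlogit,
            "bd": dlogit.sum(axis=0),
            "W": np.zeros_like(self.W),
            "U": np.zeros_like(self.U),
            "b": np.zeros_like(self.b),
        }
        dh = (dlogit @ self.Wd.T) * drop_mask
        dc = np.zeros((bsz, u))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, tanh_c, h_prev = trace[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            grads["W"] += X[:, t, :].T @ dz
            grads["U"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ self.U.T
            dc = dc * f
        loss = float(
            -np.mean(
                y * np.log(np.clip(p, 1e-12, 1)) + (1 - y) * np.log(np.clip(1 - p, 1e-12, 1))
            )
        )
        return loss, grads

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NumpyLSTM":
        """Train on (batch, T, features) inputs and 0/1 targets."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 3:
            raise ParameterError("LSTM input must be 3-axis (samples, timesteps, features)")
        if X.shape[0] != y.size:
            raise ParameterError("sample/label count mismatch")
        n = X.shape[0]
        rho, eps = 0.9, 1e-7
        self.history_: list[float] = []
        for _ in range(self.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if self.dropout > 0:
                    mask = (
                        self._rng.random((idx.size, self.units)) >= self.dropout
                    ) / (1 - self.dropout)
                else:
                    mask = np.ones((idx.size, self.units))
                loss, grads = self._bptt(X[idx], y[idx], mask)
                epoch_loss += loss * idx.size
                for k, g in grads.items():
                    norm = np.linalg.norm(g)
                    if norm > 5.0:  # norm cap against rare blow-ups
                        g = g * (5.0 / norm)
                    cache = self._cache[k]
                    cache *= rho
                    cache += (1 - rho) * g * g
                    setattr(self, k, getattr(self, k) - self.lr * g / (np.sqrt(cache) + eps))
            self.history_.append(epoch_loss / n)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability (sigmoid output) per sample."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ParameterError("LSTM input must be 3-axis (samples, timesteps, features)")
        if X.shape[0] == 0:
            return np.empty(0)
        h, _, _ = self._forward(X)
        return _sigmoid((h @ self.Wd + self.bd).ravel())
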