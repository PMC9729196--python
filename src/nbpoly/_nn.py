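"""Minimal numpy neural-network layers with manual backpropagation.

Implements exactly the pieces the convolutional and recurrent polyreactivity
classifiers need: 1D convolution, batch normalization, ReLU, 1D max pooling,
dense layers, GRU recurrence, an Adam optimizer and a binary cross-entropy
loss on logits.  Everything is plain numpy, single-threaded-deterministic
given a seed, and validated against finite-difference gradients in the test
suite.

Shapes: convolutional paths use (batch, channels, length); the GRU uses
(batch, time, features).
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameters in ``self.params``, gradients in ``self.grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self):
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Conv1D(Layer):
    def __init__(self, cin, cout, k, rng, dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / (cin * k))
        self.k = k
        self.params["W"] = (rng.standard_normal((cout, cin, k)) * scale).astype(dtype)
        self.params["b"] = np.zeros(cout, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train=True):
        self._win = sliding_window_view(x, self.k, axis=2)  # (B, Cin, Lout, k)
        out = np.einsum("bclk,ock->bol", self._win, self.params["W"], optimize=True)
        out += self.params["b"][None, :, None]
        self._xshape = x.shape
        return out

    def backward(self, dout):
        W = self.params["W"]
        self.grads["W"] += np.einsum("bclk,bol->ock", self._win, dout, optimize=True)
        self.grads["b"] += dout.sum(axis=(0, 2))
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        lout = dout.shape[2]
        for j in range(self.k):
            dx[:, :, j : j + lout] += np.einsum("bol,oc->bcl", dout, W[:, :, j], optimize=True)
        return dx


class BatchNorm1D(Layer):
    """Per-channel normalization over (batch, length) with running stats."""

    def __init__(self, channels, momentum=0.1, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train=True):
        if train:
            mu = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu[None, :, None]) * self._inv_std[None, :, None]
        return self.params["gamma"][None, :, None] * self._xhat + self.params["beta"][None, :, None]

    def backward(self, dout):
        xhat, inv_std = self._xhat, self._inv_std
        n = dout.shape[0] * dout.shape[2]
        self.grads["gamma"] += (dout * xhat).sum(axis=(0, 2))
        self.grads["beta"] += dout.sum(axis=(0, 2))
        dxhat = dout * self.params["gamma"][None, :, None]
        s1 = dxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / n) * (n * dxhat - s1 - xhat * s2)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    def __init__(self, k, stride):
        super().__init__()
        self.k, self.stride = k, stride

    def forward(self, x, train=True):
        win = sliding_window_view(x, self.k, axis=2)[:, :, :: self.stride]
        self._arg = win.argmax(axis=-1)
        self._xshape = x.shape
        return win.max(axis=-1)

    def backward(self, dout):
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        sel = np.arange(self.k)
        for i in range(dout.shape[2]):
            onehot = self._arg[:, :, i, None] == sel
            dx[:, :, i * self.stride : i * self.stride + self.k] += dout[:, :, i, None] * onehot
        return dx


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, din, dout, rng, dtype=np.float32):
        super().__init__()
        scale = np.sqrt(2.0 / din)
        self.params["W"] = (rng.standard_normal((din, dout)) * scale).astype(dtype)
        self.params["b"] = np.zeros(dout, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class GRU(Layer):
    """Single GRU layer returning hidden states for every time step.

    Gate layout follows the usual convention (reset, update, candidate) with
    separate input- and hidden-side biases, so the candidate gate is
    ``tanh(x Wxn + bxn + r * (h Whn + bhn))``.
    """

    def __init__(self, din, hidden, rng, dtype=np.float32):
        super().__init__()
        self.hidden = hidden
        s_in = np.sqrt(1.0 / din)
        s_h = np.sqrt(1.0 / hidden)
        self.params["Wx"] = (rng.standard_normal((din, 3 * hidden)) * s_in).astype(dtype)
        self.params["Wh"] = (rng.standard_normal((hidden, 3 * hidden)) * s_h).astype(dtype)
        self.params["bx"] = np.zeros(3 * hidden, dtype=dtype)
        self.params["bh"] = np.zeros(3 * hidden, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train=True):
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        bx, bh = self.params["bx"], self.params["bh"]
        h = np.zeros((B, H), dtype=x.dtype)
        self._cache = []
        out = np.empty((B, T, H), dtype=x.dtype)
        gx_all = x.reshape(B * T, -1) @ Wx  # input-side projections in one matmul
        gx_all = gx_all.reshape(B, T, 3 * H) + bx
        for t in range(T):
            gh = h @ Wh + bh
            gx = gx_all[:, t]
            r = _sigmoid(gx[:, :H] + gh[:, :H])
            z = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
            n = np.tanh(gx[:, 2 * H :] + r * gh[:, 2 * H :])
            h_prev = h
            h = (1.0 - z) * n + z * h_prev
            self._cache.append((h_prev, r, z, n, gh[:, 2 * H :]))
            out[:, t] = h
        self._x = x
        return out

    def backward(self, dout):
        x = self._x
        B, T, D = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dgx_all = np.zeros((B, T, 3 * H), dtype=dout.dtype)
        dh = np.zeros((B, H), dtype=dout.dtype)
        dWh = np.zeros_like(Wh)
        dbh = np.zeros_like(self.params["bh"])
        for t in reversed(range(T)):
            h_prev, r, z, n, ghn = self._cache[t]
            dht = dout[:, t] + dh
            dz = dht * (h_prev - n)
            dn = dht * (1.0 - z)
            dh = dht * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * ghn
            dr_pre = dr * r * (1.0 - r)
            dz_pre = dz * z * (1.0 - z)
            dgx = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            dgh = np.concatenate([dr_pre, dz_pre, dn_pre * r], axis=1)
            dgx_all[:, t] = dgx
            dWh += h_prev.T @ dgh
            dbh += dgh.sum(axis=0)
            dh += dgh @ Wh.T
        flat = dgx_all.reshape(B * T, 3 * H)
        self.grads["Wx"] += x.reshape(B * T, D).T @ flat
        self.grads["bx"] += flat.sum(axis=0)
        self.grads["Wh"] += dWh
        self.grads["bh"] += dbh
        return (flat @ Wx.T).reshape(B, T, D)


class LastStep(Layer):
    """Select the final time step of a (batch, time, features) sequence."""

    def forward(self, x, train=True):
        self._shape = x.shape
        return x[:, -1]

    def backward(self, dout):
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, -1] = dout
        return dx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def state(self):
        """Deep copy of all parameters and batch-norm running statistics."""
        st = []
        for layer in self.layers:
            entry = {k: v.copy() for k, v in layer.params.items()}
            if isinstance(layer, BatchNorm1D):
                entry["__rm"] = layer.running_mean.copy()
                entry["__rv"] = layer.running_var.copy()
            st.append(entry)
        return st

    def load_state(self, st):
        for layer, entry in zip(self.layers, st):
            for k in layer.params:
                layer.params[k] = entry[k].copy()
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = entry["__rm"].copy()
                layer.running_var = entry["__rv"].copy()
            layer.zero_grad()


def bce_with_logits(logits, y):
    """Mean binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits.ravel()
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    dz = (_sigmoid(z) - y) / z.size
    return loss, dz.reshape(logits.shape)


class Adam:
    def __init__(self, net: Sequential, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in net.layers]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, layer in enumerate(self.net.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / b1t
                vhat = self.v[i][k] / b2t
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_cnn(n_slots: int, seed: int, dtype=np.float32) -> Sequential:
    """Three-block 1D CNN on the aligned one-hot grid (20 input channels).

    conv(20->32, k3)+BN+ReLU; conv(32->64, k3)+BN+ReLU+maxpool(k3, s3);
    conv(64->128, k3)+BN+ReLU+maxpool(k3, s1); dense to one logit.
    """
    rng = np.random.default_rng(seed)
    length = n_slots
    layers: list[Layer] = []
    layers += [Conv1D(20, 32, 3, rng, dtype), BatchNorm1D(32, dtype=dtype), ReLU()]
    length -= 2
    layers += [Conv1D(32, 64, 3, rng, dtype), BatchNorm1D(64, dtype=dtype), ReLU(), MaxPool1D(3, 3)]
    length = (length - 2 - 3) // 3 + 1
    layers += [Conv1D(64, 128, 3, rng, dtype), BatchNorm1D(128, dtype=dtype), ReLU(), MaxPool1D(3, 1)]
    length = (length - 2 - 3) // 1 + 1
    if length < 1:
        raise ValueError(f"input length {n_slots} too short for the CNN stack")
    layers += [Flatten(), Dense(128 * length, 1, rng, dtype)]
    return Sequential(layers)


def build_gru(max_len: int, seed: int, hidden: int = 128, n_layers: int = 2, dtype=np.float32) -> Sequential:
    """Stacked GRU on unaligned padded one-hot input, last state to a logit."""
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    din = 20
    for _ in range(n_layers):
        layers.append(GRU(din, hidden, rng, dtype))
        din = hidden
    layers += [LastStep(), Dense(hidden, 1, rng, dtype)]
    return Sequential(layers)


def fit_network(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 20,
    batch_size: int = 256,
    lr: float = 1e-3,
    seed: int = 0,
    val_frac: float = 0.1,
    patience: int = 3,
) -> dict:
    """Adam minibatch training with early stopping on a validation split.

    The best-validation parameters are restored at the end.  Fully
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_frac * n))) if val_frac > 0 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = Adam(net, lr=lr)
    best_loss = np.inf
    best_state = net.state()
    bad_epochs = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(epochs):
        order = rng.permutation(len(Xtr))
        ep_loss = 0.0
        for start in range(0, len(Xtr), batch_size):
            idx = order[start : start + batch_size]
            net.zero_grad()
            logits = net.forward(Xtr[idx], train=True)
            loss, dlogits = bce_with_logits(logits, ytr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * len(idx)
        history["train_loss"].append(ep_loss / len(Xtr))
        if n_val:
            val_logits = predict_logits(net, Xval)
            val_loss, _ = bce_with_logits(val_logits, yval)
            history["val_loss"].append(val_loss)
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_state = net.state()
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs > patience:
                    break
    if n_val:
        net.load_state(best_state)
    return history


def predict_logits(net: Sequential, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
    parts = [
        net.forward(X[i : i + batch_size], train=False).ravel()
        for i in range(0, X.shape[0], batch_size)
    ]
    return np.concatenate(parts) if parts else np.empty(0)
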