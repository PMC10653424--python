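"""Minimal NumPy neural-network core used by the expression model.

Implements exactly the layer types the predictor needs — 1-D valid
convolution, non-overlapping max pooling, ReLU/ELU, inverted dropout,
batch normalization and dense layers — with hand-written backward passes
and a decoupled-weight-decay Adam (AdamW) optimizer. Everything runs in
float32 on the CPU and is deterministic given the seeds of the generators
handed to the stochastic layers.

Data layout: sequence tensors are ``(batch, length, channels)``; dense
tensors are ``(batch, features)``. Convolutions are "valid" (no padding),
so an output position always corresponds to a full kernel-width window of
the input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base class: forward caches what backward needs; params/grads/buffers
    are plain dicts so the whole model state can be snapshotted cheaply."""

    frozen = False

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = None


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 1.0):
        super().__init__()
        std = gain * np.sqrt(1.0 / n_in)
        self.params["W"] = rng.normal(0.0, std, (n_in, n_out)).astype(DTYPE)
        self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Conv1d(Layer):
    """Valid 1-D convolution, stride 1.

    Weights are stored flattened as ``(channels * klen, kernels)`` with the
    channel index major, so a pre-computed im2col matrix of an input
    sequence can be fed directly through :meth:`forward_col`.
    """

    def __init__(self, n_channels: int, n_kernels: int, klen: int,
                 rng: np.random.Generator):
        super().__init__()
        self.n_channels = n_channels
        self.n_kernels = n_kernels
        self.klen = klen
        fan_in = n_channels * klen
        std = np.sqrt(2.0 / fan_in)  # He init; ReLU follows in the model
        self.params["W"] = rng.normal(0.0, std, (fan_in, n_kernels)).astype(DTYPE)
        self.params["b"] = np.zeros(n_kernels, dtype=DTYPE)

    def kernels(self) -> np.ndarray:
        """Weights as ``(n_kernels, n_channels, klen)``."""
        return np.ascontiguousarray(
            self.params["W"].T.reshape(self.n_kernels, self.n_channels, self.klen))

    def im2col(self, x: np.ndarray) -> np.ndarray:
        """``(B, L, C)`` -> ``(B, L-k+1, C*k)`` window matrix."""
        w = sliding_window_view(x, self.klen, axis=1)  # (B, Lout, C, k)
        B, Lout = w.shape[0], w.shape[1]
        return np.ascontiguousarray(w).reshape(B, Lout, self.n_channels * self.klen)

    def forward(self, x, train):
        self._L = x.shape[1]
        return self.forward_col(self.im2col(x), train)

    def forward_col(self, xcol, train):
        self._xcol = xcol
        B, Lout, F = xcol.shape
        y = xcol.reshape(B * Lout, F) @ self.params["W"]
        return y.reshape(B, Lout, self.n_kernels) + self.params["b"]

    def backward(self, dy, need_dx: bool = True):
        B, Lout, K = dy.shape
        dyf = dy.reshape(B * Lout, K)
        self.grads["W"] = self._xcol.reshape(B * Lout, -1).T @ dyf
        self.grads["b"] = dyf.sum(axis=0)
        if not need_dx:
            return None
        dxcol = (dyf @ self.params["W"].T).reshape(
            B, Lout, self.n_channels, self.klen)
        L = getattr(self, "_L", Lout + self.klen - 1)
        dx = np.zeros((B, L, self.n_channels), dtype=DTYPE)
        for j in range(self.klen):
            dx[:, j:j + Lout, :] += dxcol[:, :, :, j]
        return dx


class MaxPool1d(Layer):
    """Non-overlapping max pooling (kernel size == stride); a trailing
    remainder shorter than the kernel is discarded (floor semantics)."""

    def __init__(self, size: int):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        B, L, C = x.shape
        Lp = L // self.size
        self._shape = (B, L, C)
        xr = x[:, :Lp * self.size, :].reshape(B, Lp, self.size, C)
        # eval-mode forwards never backprop, so skip the argmax bookkeeping
        self._idx = xr.argmax(axis=2) if train else None
        return xr.max(axis=2)

    def backward(self, dy):
        B, L, C = self._shape
        Lp = dy.shape[1]
        dxr = np.zeros((B, Lp, self.size, C), dtype=DTYPE)
        np.put_along_axis(dxr, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=DTYPE)
        dx[:, :Lp * self.size, :] = dxr.reshape(B, Lp * self.size, C)
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, dy):
        return dy * self._mask


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train):
        self._pos = x > 0
        y = np.where(self._pos, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._y = y.astype(DTYPE, copy=False)
        return self._y

    def backward(self, dy):
        return dy * np.where(self._pos, 1.0, self._y + self.alpha).astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0,1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (channel) axis,
    with learnable affine parameters and running statistics for eval mode."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params["gamma"] = np.ones(n_features, dtype=DTYPE)
        self.params["beta"] = np.zeros(n_features, dtype=DTYPE)
        self.buffers["running_mean"] = np.zeros(n_features, dtype=DTYPE)
        self.buffers["running_var"] = np.ones(n_features, dtype=DTYPE)

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        self._train = train
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"] = ((1 - m) * self.buffers["running_mean"]
                                            + m * mean).astype(DTYPE)
            self.buffers["running_var"] = ((1 - m) * self.buffers["running_var"]
                                           + m * var).astype(DTYPE)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        self._xhat = xhat.astype(DTYPE, copy=False)
        self._invstd = invstd.astype(DTYPE, copy=False)
        self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy):
        axes = tuple(range(dy.ndim - 1))
        self.grads["gamma"] = (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        if not self._train:
            return dy * g * self._invstd
        dxhat = dy * g
        m = self._m
        s1 = dxhat.sum(axis=axes)
        s2 = (dxhat * self._xhat).sum(axis=axes)
        return (self._invstd / m) * (m * dxhat - s1 - self._xhat * s2)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Sequential:
    """Ordered stack of layers with a shared name prefix for state dicts."""

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers

    def forward(self, x, train):
        for _, layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy, stop_before_first_dx: bool = False):
        for i, (_, layer) in enumerate(reversed(self.layers)):
            last = i == len(self.layers) - 1
            if last and stop_before_first_dx and isinstance(layer, Conv1d):
                layer.backward(dy, need_dx=False)
                return None
            dy = layer.backward(dy)
        return dy

    def named_layers(self, prefix: str):
        for name, layer in self.layers:
            yield f"{prefix}.{name}", layer


class AdamW:
    """Adam with decoupled weight decay. Parameters belonging to layers with
    ``frozen=True`` are skipped entirely (used for transfer learning)."""

    def __init__(self, modules: list[tuple[str, Layer]], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.entries = [(name, layer, pname)
                        for name, layer in modules
                        for pname in layer.params]
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {f"{n}.{p}": np.zeros_like(l.params[p])
                  for n, l, p in self.entries}
        self.v = {f"{n}.{p}": np.zeros_like(l.params[p])
                  for n, l, p in self.entries}

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for name, layer, pname in self.entries:
            if layer.frozen:
                continue
            g = layer.grads.get(pname)
            if g is None:
                continue
            key = f"{name}.{pname}"
            p = layer.params[pname]
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            update = (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p -= (self.lr * update + self.lr * self.weight_decay * p).astype(p.dtype)

    def zero_grad(self):
        for _, layer, pname in self.entries:
            layer.grads[pname] = None


def state_dict(modules: list[tuple[str, Layer]]) -> dict[str, np.ndarray]:
    state = {}
    for name, layer in modules:
        for pname, arr in layer.params.items():
            state[f"{name}.{pname}"] = arr.copy()
        for bname, arr in layer.buffers.items():
            state[f"{name}.buf.{bname}"] = arr.copy()
    return state


def load_state_dict(modules: list[tuple[str, Layer]],
                    state: dict[str, np.ndarray]) -> None:
    for name, layer in modules:
        for pname in layer.params:
            layer.params[pname] = state[f"{name}.{pname}"].copy()
        for bname in layer.buffers:
            layer.buffers[bname] = state[f"{name}.buf.{bname}"].copy()
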