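"""Minimal NumPy neural-network layers with explicit backprop.

All layers operate on NHWC float32 tensors (or NC for dense stages) and
implement three things: ``forward``, ``backward`` (input gradient, optionally
accumulating parameter gradients), and parameter enumeration for the
optimizer.  Convolutions are 3x3, stride 1, realised as im2col + BLAS
matmul, which is the fastest portable route on a single CPU.

The backward pass supports a ``guided`` flag: at every ReLU the backward
signal is zeroed where either the forward activation or the incoming
backward signal is negative (guided backpropagation).
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K

F32 = np.float32


class Layer:
    """Base class; layers are stateful (they cache the last forward pass)."""

    params: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, training=False, rng=None):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy, param_grads=True, guided=False):  # pragma: no cover
        raise NotImplementedError

    def zero_grads(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    @property
    def n_params(self) -> int:
        return sum(int(v.size) for v in self.params.values())


def xavier_uniform(rng: np.random.Generator, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(F32)


class Conv2D(Layer):
    """3x3 stride-1 convolution, 'same' or 'valid' padding, optional ReLU.

    Weights are stored as (out_channels, in_channels, 3, 3), matching the
    (d_i, d_{i-1}, m, m) layout used by weight marginalization.

    The convolution is computed as nine shifted (pixels x channels) matmuls
    accumulated into the output — much cheaper on large images than
    materializing an im2col patch matrix.
    """

    def __init__(self, in_ch, out_ch, pad, relu=True, rng=None):
        super().__init__()
        assert pad in ("same", "valid")
        self.in_ch, self.out_ch, self.pad, self.relu = in_ch, out_ch, pad, relu
        rng = rng or np.random.default_rng(0)
        fan_in, fan_out = in_ch * 9, out_ch * 9
        self.params = {
            "W": xavier_uniform(rng, (out_ch, in_ch, 3, 3), fan_in, fan_out),
            "b": np.zeros(out_ch, dtype=F32),
        }

    def forward(self, x, training=False, rng=None):
        x = np.ascontiguousarray(x, dtype=F32)
        if self.pad == "same":
            xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        else:
            xp = x
        n, hp, wp, _ = xp.shape
        ho, wo = hp - 2, wp - 2
        W = self.params["W"]
        xp2 = xp.reshape(-1, self.in_ch)
        z = np.empty((n, ho, wo, self.out_ch), dtype=F32)
        z[:] = self.params["b"]
        buf = np.empty((xp2.shape[0], self.out_ch), dtype=F32)
        buf4 = buf.reshape(n, hp, wp, self.out_ch)
        for ki in range(3):
            for kj in range(3):
                np.matmul(xp2, W[:, :, ki, kj].T, out=buf)
                z += buf4[:, ki:ki + ho, kj:kj + wo, :]
        self._xp = xp if training else None
        self._shape = (n, ho, wo, hp, wp)
        if self.relu:
            self._mask = z > 0
            z = np.where(self._mask, z, 0)
        return z

    def backward(self, dy, param_grads=True, guided=False, need_input_grad=True):
        n, ho, wo, hp, wp = self._shape
        if self.relu:
            gate = self._mask
            if guided:
                gate = gate & (dy > 0)
            dy = np.where(gate, dy, 0)
        W = self.params["W"]
        dy = np.ascontiguousarray(dy, dtype=F32)
        dy2 = dy.reshape(-1, self.out_ch)
        if param_grads:
            if self._xp is None:
                raise RuntimeError("parameter gradients need a training-mode forward")
            xp2 = self._xp.reshape(-1, self.in_ch)
            dyz = np.zeros((n, hp, wp, self.out_ch), dtype=F32)
            dyz2 = dyz.reshape(-1, self.out_ch)
            for ki in range(3):
                for kj in range(3):
                    dyz.fill(0.0)
                    dyz[:, ki:ki + ho, kj:kj + wo, :] = dy
                    self.grads["W"][:, :, ki, kj] += (xp2.T @ dyz2).T
            self.grads["b"] += dy2.sum(axis=0)
        if not need_input_grad:
            return None
        dxp = np.zeros((n, hp, wp, self.in_ch), dtype=F32)
        buf = np.empty((dy2.shape[0], self.in_ch), dtype=F32)
        buf4 = buf.reshape(n, ho, wo, self.in_ch)
        for ki in range(3):
            for kj in range(3):
                np.matmul(dy2, W[:, :, ki, kj], out=buf)
                dxp[:, ki:ki + ho, kj:kj + wo, :] += buf4
        if self.pad == "same":
            return dxp[:, 1:-1, 1:-1, :]
        return dxp


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, floor division on odd spatial dims.

    Backward routes the gradient to the first maximum in each window
    (deterministic tie-break)."""

    factor = 2

    def forward(self, x, training=False, rng=None):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        if K.HAVE_NUMBA:
            x = np.ascontiguousarray(x, dtype=F32)
            out = np.empty((n, h2, w2, c), dtype=F32)
            idx = np.empty((n, h2, w2, c), dtype=np.int8)
            K.maxpool2_fwd(x, out, idx)
            self._idx = idx
            return out
        xc = x[:, : h2 * 2, : w2 * 2, :]
        win = xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
        self._idx = win.argmax(axis=4)
        return np.take_along_axis(win, self._idx[..., None], axis=4)[..., 0]

    def backward(self, dy, param_grads=True, guided=False):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        if K.HAVE_NUMBA:
            dx = np.zeros((n, h, w, c), dtype=F32)
            K.maxpool2_bwd(np.ascontiguousarray(dy, dtype=F32), self._idx, dx)
            return dx
        dwin = np.zeros((n, h2, w2, c, 4), dtype=F32)
        np.put_along_axis(dwin, self._idx[..., None], dy[..., None], axis=4)
        dxc = dwin.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(n, h2 * 2, w2 * 2, c)
        if h2 * 2 == h and w2 * 2 == w:
            return dxc
        dx = np.zeros((n, h, w, c), dtype=F32)
        dx[:, : h2 * 2, : w2 * 2, :] = dxc
        return dx


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy, param_grads=True, guided=False):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    """Fully connected layer with 'relu', 'sigmoid' or 'none' activation."""

    def __init__(self, in_dim, out_dim, activation="relu", rng=None):
        super().__init__()
        assert activation in ("relu", "sigmoid", "none")
        self.in_dim, self.out_dim, self.activation = in_dim, out_dim, activation
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": xavier_uniform(rng, (in_dim, out_dim), in_dim, out_dim),
            "b": np.zeros(out_dim, dtype=F32),
        }

    def forward(self, x, training=False, rng=None):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._z = z
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0)
        if self.activation == "sigmoid":
            with np.errstate(over="ignore"):
                self._s = 1.0 / (1.0 + np.exp(-z))
            return self._s
        return z

    def backward(self, dy, param_grads=True, guided=False, dy_is_preact=False):
        if dy_is_preact:
            dz = dy
        elif self.activation == "relu":
            gate = self._mask
            if guided:
                gate = gate & (dy > 0)
            dz = np.where(gate, dy, 0)
        elif self.activation == "sigmoid":
            dz = dy * self._s * (1.0 - self._s)
        else:
            dz = dy
        if param_grads:
            self.grads["W"] += self._x.T @ dz
            self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class BatchNorm1D(Layer):
    """Batch normalization over feature vectors (used after the 2nd dense)."""

    def __init__(self, dim, momentum=0.9, eps=1e-5):
        super().__init__()
        self.dim, self.momentum, self.eps = dim, momentum, eps
        self.params = {"gamma": np.ones(dim, dtype=F32), "beta": np.zeros(dim, dtype=F32)}
        self.running_mean = np.zeros(dim, dtype=F32)
        self.running_var = np.ones(dim, dtype=F32)

    def forward(self, x, training=False, rng=None):
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mu) / self._std
            self._training = True
            return self.params["gamma"] * self._xhat + self.params["beta"]
        self._training = False
        self._std = np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * (x - self.running_mean) / self._std + self.params["beta"]

    def backward(self, dy, param_grads=True, guided=False):
        g = self.params["gamma"]
        if not self._training:
            return dy * g / self._std
        if param_grads:
            self.grads["gamma"] += (dy * self._xhat).sum(axis=0)
            self.grads["beta"] += dy.sum(axis=0)
        n = dy.shape[0]
        dxhat = dy * g
        return (dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)) / self._std


class BatchNorm2D(Layer):
    """Per-channel batch normalization on NHWC maps (optional, after conv blocks)."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.params = {"gamma": np.ones(channels, dtype=F32), "beta": np.zeros(channels, dtype=F32)}
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)

    def forward(self, x, training=False, rng=None):
        axes = (0, 1, 2)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - mu) / self._std
            self._training = True
            return self.params["gamma"] * self._xhat + self.params["beta"]
        self._training = False
        self._std = np.sqrt(self.running_var + self.eps)
        return self.params["gamma"] * (x - self.running_mean) / self._std + self.params["beta"]

    def backward(self, dy, param_grads=True, guided=False):
        g = self.params["gamma"]
        if not self._training:
            return dy * g / self._std
        if param_grads:
            self.grads["gamma"] += (dy * self._xhat).sum(axis=(0, 1, 2))
            self.grads["beta"] += dy.sum(axis=(0, 1, 2))
        axes = (0, 1, 2)
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        dxhat = dy * g
        return (dxhat - dxhat.sum(axes) / m - self._xhat * (dxhat * self._xhat).sum(axes) / m) / self._std


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dy, param_grads=True, guided=False):
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam optimizer over the parameter dicts of a list of layers."""

    def __init__(self, layers, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k]
                v = self.v[li][k]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= (lr * (m / c1) / (np.sqrt(v / c2) + self.eps)).astype(p.dtype)
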