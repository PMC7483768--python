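"""Trainable layers with explicit forward/backward passes.

Each layer holds its parameters and accumulated gradients in dicts keyed by
name; :class:`~cribnet.nn.model.SegmentationNetwork` walks the layer tree to
collect, checkpoint and update them.  Tensors are channels-first (N, C, H, W).
"""

from __future__ import annotations

import numpy as np

from . import ops


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
               dtype=np.float32) -> np.ndarray:
    """Fan-in-scaled uniform initialization U(-sqrt(6/fan_in), +sqrt(6/fan_in))."""
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def children(self) -> list["Layer"]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3x3(Layer):
    def __init__(self, rng, c_in: int, c_out: int, dtype=np.float32) -> None:
        super().__init__()
        self.params["w"] = he_uniform(rng, (c_out, c_in, 3, 3), c_in * 9, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.skip_input_grad = False   # set on the input-facing convolution
        self._xp = None

    def forward(self, x, train):
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        self._xp = xp if train else None
        y = np.empty((x.shape[0], self.params["w"].shape[0], x.shape[2], x.shape[3]),
                     dtype=x.dtype)
        ops.conv3x3_forward(xp, self.params["w"], self.params["b"], y)
        return y

    def backward(self, dy):
        if self.skip_input_grad:
            dw = np.empty_like(self.params["w"])
            ops.conv3x3_dw(self._xp, dy, dw)
            self.grads["w"] = dw
            self.grads["b"] = dy.sum(axis=(0, 2, 3))
            self._xp = None
            return 0.0
        dx, dw, db = ops.conv3x3_backward(self._xp, self.params["w"], dy)
        self.grads["w"] = dw
        self.grads["b"] = db
        self._xp = None
        return dx


class Conv2x2Down(Layer):
    """2x2 stride-2 convolution (learned downsampling between blocks)."""

    def __init__(self, rng, c_in: int, c_out: int, dtype=np.float32) -> None:
        super().__init__()
        self.params["w"] = he_uniform(rng, (c_out, c_in, 2, 2), c_in * 4, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self._x = None

    def forward(self, x, train):
        self._x = x if train else None
        return ops.conv2x2s2(x, self.params["w"], self.params["b"])

    def backward(self, dy):
        dx, dw, db = ops.conv2x2s2_backward(self._x, self.params["w"], dy)
        self.grads["w"] = dw
        self.grads["b"] = db
        self._x = None
        return dx


class Conv1x1(Layer):
    def __init__(self, rng, c_in: int, c_out: int, dtype=np.float32) -> None:
        super().__init__()
        self.params["w"] = he_uniform(rng, (c_out, c_in), c_in, dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self.skip_input_grad = False
        self._x = None

    def forward(self, x, train):
        self._x = x if train else None
        return ops.conv1x1(x, self.params["w"], self.params["b"])

    def backward(self, dy):
        if self.skip_input_grad:
            self.grads["w"] = np.einsum("nohw,nchw->oc", dy, self._x,
                                        optimize=True).astype(self.params["w"].dtype)
            self.grads["b"] = dy.sum(axis=(0, 2, 3))
            self._x = None
            return 0.0
        dx, dw, db = ops.conv1x1_backward(self._x, self.params["w"], dy)
        self.grads["w"] = dw
        self.grads["b"] = db
        self._x = None
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization; inference uses running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=dtype)
        self.params["beta"] = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train):
        if train:
            out = np.empty_like(x)
            xhat = np.empty_like(x)
            mean = np.empty(x.shape[1], dtype=x.dtype)
            var = np.empty(x.shape[1], dtype=x.dtype)
            ops.bn_forward_train(x, self.params["gamma"], self.params["beta"],
                                 x.dtype.type(self.eps), out, xhat, mean, var)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean.astype(np.float64))
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.astype(np.float64))
            invstd = (1.0 / np.sqrt(var.astype(np.float64)
                                    + self.eps)).astype(x.dtype)
            self._cache = (xhat, invstd)
            return out
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        mean = self.running_mean.astype(x.dtype)
        var = self.running_var.astype(x.dtype)
        invstd = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.dtype)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        return (g * xhat + b).astype(x.dtype)

    def backward(self, dy):
        xhat, invstd = self._cache
        self._cache = None
        dx = np.empty_like(dy)
        dgamma = np.empty_like(self.params["gamma"])
        dbeta = np.empty_like(self.params["beta"])
        ops.bn_backward(xhat, self.params["gamma"], invstd, dy, dx,
                        dgamma, dbeta)
        self.grads["gamma"] = dgamma
        self.grads["beta"] = dbeta
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x, train):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx


class SqueezeExcite(Layer):
    """Channel attention: global pool -> bottleneck MLP -> sigmoid gating."""

    def __init__(self, rng, channels: int, reduction: int = 16,
                 dtype=np.float32) -> None:
        super().__init__()
        hidden = max(1, channels // reduction)
        self.params["w1"] = he_uniform(rng, (channels, hidden), channels, dtype)
        self.params["b1"] = np.zeros(hidden, dtype=dtype)
        self.params["w2"] = he_uniform(rng, (hidden, channels), hidden, dtype)
        self.params["b2"] = np.zeros(channels, dtype=dtype)
        self._cache = None

    def forward(self, x, train):
        z = x.mean(axis=(2, 3))                              # (N, C)
        h = np.maximum(z @ self.params["w1"] + self.params["b1"], 0)
        s = 1.0 / (1.0 + np.exp(-(h @ self.params["w2"] + self.params["b2"])))
        s = s.astype(x.dtype)
        if train:
            self._cache = (x, z, h, s)
        return x * s[:, :, None, None]

    def backward(self, dy):
        x, z, h, s = self._cache
        self._cache = None
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))
        dpre2 = ds * s * (1.0 - s)
        self.grads["w2"] = h.T @ dpre2
        self.grads["b2"] = dpre2.sum(axis=0)
        dh = dpre2 @ self.params["w2"].T
        dpre1 = dh * (h > 0)
        self.grads["w1"] = z.T @ dpre1
        self.grads["b1"] = dpre1.sum(axis=0)
        dz = dpre1 @ self.params["w1"].T
        dx += (dz / (x.shape[2] * x.shape[3]))[:, :, None, None]
        return dx.astype(dy.dtype)


class ResidualSEBlock(Layer):
    """Two 3x3 convolutions with SE recalibration and an additive shortcut.

    Layout: conv-BN-ReLU-conv-BN-SE, plus the identity (or a 1x1
    projection+BN when the channel count changes), then a final ReLU.
    """

    def __init__(self, rng, c_in: int, c_out: int, se_reduction: int = 16,
                 dtype=np.float32) -> None:
        super().__init__()
        self.conv1 = Conv3x3(rng, c_in, c_out, dtype)
        self.bn1 = BatchNorm(c_out, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv3x3(rng, c_out, c_out, dtype)
        self.bn2 = BatchNorm(c_out, dtype=dtype)
        self.se = SqueezeExcite(rng, c_out, se_reduction, dtype)
        self.proj = None
        self.bn_proj = None
        if c_in != c_out:
            self.proj = Conv1x1(rng, c_in, c_out, dtype)
            self.bn_proj = BatchNorm(c_out, dtype=dtype)
        self.relu_out = ReLU()

    def children(self):
        out = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.se]
        if self.proj is not None:
            out += [self.proj, self.bn_proj]
        return out + [self.relu_out]

    def forward(self, x, train):
        t = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train),
                               train)
        t = self.se.forward(self.bn2.forward(self.conv2.forward(t, train), train),
                            train)
        if self.proj is not None:
            sc = self.bn_proj.forward(self.proj.forward(x, train), train)
        else:
            sc = x
        return self.relu_out.forward(t + sc, train)

    def backward(self, dy):
        d = self.relu_out.backward(dy)
        dmain = self.conv1.backward(self.bn1.backward(self.relu1.backward(
            self.conv2.backward(self.bn2.backward(self.se.backward(d))))))
        if self.proj is not None:
            dsc = self.proj.backward(self.bn_proj.backward(d))
        else:
            dsc = d
        return dmain + dsc
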