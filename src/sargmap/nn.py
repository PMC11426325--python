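"""Minimal convolutional-network building blocks in numpy.

Implements exactly the layer set the conditional-GAN segmenter needs — 4x4
convolutions and transposed convolutions, batch normalization, LeakyReLU /
ReLU / Tanh, dropout — each with a hand-written backward pass, plus the Adam
optimizer. Convolutions are evaluated by im2col + matrix multiply; the
transposed convolution is the exact adjoint (col2im) of the matching
convolution, so gradient checks close to machine precision.

Shapes follow the (N, C, H, W) convention in float32. Every layer caches what
its backward pass needs during ``forward``; ``backward`` consumes the cache,
stores parameter gradients in ``layer.grads``, and returns the gradient with
respect to the layer input.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "Layer", "Conv2d", "ConvTranspose2d", "BatchNorm2d",
    "LeakyReLU", "ReLU", "Tanh", "Dropout", "Adam",
    "bce_with_logits", "bce_with_logits_grad", "sigmoid",
]

_DT = np.float32


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, target: float) -> float:
    """Mean binary cross-entropy against a constant 0/1 target, from logits."""
    z = np.asarray(z, dtype=np.float64)
    return float(np.mean(np.maximum(z, 0) - z * target + np.log1p(np.exp(-np.abs(z)))))


def bce_with_logits_grad(z: np.ndarray, target: float) -> np.ndarray:
    """d(mean BCE)/dz = (sigmoid(z) - target) / count."""
    return ((sigmoid(z) - target) / z.size).astype(_DT)


# ---------------------------------------------------------------------------
# im2col / col2im


def _im2col(xp: np.ndarray, k: int, s: int) -> Tuple[np.ndarray, int, int]:
    """Padded (N,C,Hp,Wp) -> (N, Ho*Wo, C*k*k) patch matrix."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    v = v[:, :, ::s, ::s]
    n, c, ho, wo = v.shape[:4]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, ho * wo, c * k * k)
    return cols, ho, wo


def _col2im(dcols: np.ndarray, n: int, c: int, hp: int, wp: int,
            ho: int, wo: int, k: int, s: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patches back into a padded array."""
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    out = np.zeros((n, c, hp, wp), dtype=_DT)
    for u in range(k):
        for v in range(k):
            out[:, :, u:u + (ho - 1) * s + 1:s,
                v:v + (wo - 1) * s + 1:s] += d[:, :, :, :, u, v]
    return out


class Layer:
    """Base: parameter dict, gradient dict, non-trainable buffer dict."""

    def __init__(self):
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}
        self.buffers: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_trainable(self) -> int:
        return sum(p.size for p in self.params.values())

    def n_non_trainable(self) -> int:
        return sum(b.size for b in self.buffers.values())


class Conv2d(Layer):
    """4x4-style convolution, weight (C_out, C_in, k, k), optional bias."""

    def __init__(self, c_in: int, c_out: int, k: int = 4, stride: int = 2,
                 pad: int = 1, bias: bool = True,
                 rng: Optional[np.random.Generator] = None,
                 init_std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k, self.s, self.p = c_in, c_out, k, stride, pad
        self.params["W"] = rng.normal(0.0, init_std,
                                      (c_out, c_in, k, k)).astype(_DT)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=_DT)
        self._cache = None

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=_DT)
        n = x.shape[0]
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        cols, ho, wo = _im2col(xp, self.k, self.s)
        wm = self.params["W"].reshape(self.c_out, -1)
        y = cols @ wm.T
        if "b" in self.params:
            y += self.params["b"]
        self._cache = (cols, xp.shape, ho, wo)
        return np.ascontiguousarray(
            y.transpose(0, 2, 1).reshape(n, self.c_out, ho, wo))

    def backward(self, dy):
        cols, xpshape, ho, wo = self._cache
        n, _, hp, wp = xpshape
        dyf = np.ascontiguousarray(
            dy.transpose(0, 2, 3, 1)).reshape(n, ho * wo, self.c_out)
        self.grads["W"] = np.tensordot(
            dyf, cols, axes=([0, 1], [0, 1])).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dyf.sum(axis=(0, 1))
        dcols = dyf @ self.params["W"].reshape(self.c_out, -1)
        dxp = _col2im(dcols, n, self.c_in, hp, wp, ho, wo, self.k, self.s)
        if self.p:
            return dxp[:, :, self.p:-self.p, self.p:-self.p]
        return dxp


class ConvTranspose2d(Layer):
    """Transposed convolution, weight (C_in, C_out, k, k), optional bias.

    Forward is the exact adjoint (col2im) of the matching stride-s
    convolution, so a 4x4 / stride-2 / pad-1 layer doubles spatial extent.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 4, stride: int = 2,
                 pad: int = 1, bias: bool = True,
                 rng: Optional[np.random.Generator] = None,
                 init_std: float = 0.02):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.k, self.s, self.p = c_in, c_out, k, stride, pad
        self.params["W"] = rng.normal(0.0, init_std,
                                      (c_in, c_out, k, k)).astype(_DT)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=_DT)
        self._cache = None

    def _out_size(self, h: int) -> int:
        return (h - 1) * self.s - 2 * self.p + self.k

    def forward(self, x, train=True):
        x = np.asarray(x, dtype=_DT)
        n, _, h, w = x.shape
        hy, wy = self._out_size(h), self._out_size(w)
        hp, wp = hy + 2 * self.p, wy + 2 * self.p
        xf = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(n, h * w, self.c_in)
        wm = self.params["W"].reshape(self.c_in, -1)   # (C_in, C_out*k*k)
        dcols = xf @ wm
        y = _col2im(dcols, n, self.c_out, hp, wp, h, w, self.k, self.s)
        if self.p:
            y = y[:, :, self.p:-self.p, self.p:-self.p]
        y = np.ascontiguousarray(y)
        if "b" in self.params:
            y += self.params["b"][None, :, None, None]
        self._cache = (xf, (n, h, w), (hy, wy))
        return y

    def backward(self, dy):
        xf, (n, h, w), _ = self._cache
        dyp = np.pad(dy.astype(_DT),
                     ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        dycols, ho, wo = _im2col(dyp, self.k, self.s)   # ho=h, wo=w
        wm = self.params["W"].reshape(self.c_in, -1)
        self.grads["W"] = np.tensordot(
            xf, dycols, axes=([0, 1], [0, 1])).reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dy.sum(axis=(0, 2, 3))
        dxf = dycols @ wm.T
        return np.ascontiguousarray(
            dxf.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2))


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    The running mean/variance are the non-trainable parameters; updates use
    exponential averaging of the (biased) batch statistics. Evaluation mode
    normalizes with the running statistics.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=_DT)
        self.params["beta"] = np.zeros(c, dtype=_DT)
        self.buffers["running_mean"] = np.zeros(c, dtype=_DT)
        self.buffers["running_var"] = np.ones(c, dtype=_DT)
        self._cache = None

    def forward(self, x, train=True, update_running=None):
        """``train`` selects batch statistics; ``update_running`` (defaults
        to ``train``) controls whether the running buffers are refreshed, so
        inference can normalize per sample without mutating the model."""
        x = np.asarray(x, dtype=_DT)
        if update_running is None:
            update_running = train
        if train:
            m = x.mean(axis=(0, 2, 3))
            v = x.var(axis=(0, 2, 3))
            if update_running:
                self.buffers["running_mean"] *= 1 - self.momentum
                self.buffers["running_mean"] += self.momentum * m
                self.buffers["running_var"] *= 1 - self.momentum
                self.buffers["running_var"] += self.momentum * v
        else:
            m = self.buffers["running_mean"]
            v = self.buffers["running_var"]
        ivstd = 1.0 / np.sqrt(v + self.eps)
        xhat = (x - m[None, :, None, None]) * ivstd[None, :, None, None]
        y = self.params["gamma"][None, :, None, None] * xhat \
            + self.params["beta"][None, :, None, None]
        self._cache = (xhat, ivstd.astype(_DT), x.shape, train)
        return y.astype(_DT)

    def backward(self, dy):
        xhat, ivstd, shape, train = self._cache
        n_, _, h_, w_ = shape
        m = n_ * h_ * w_
        g = self.params["gamma"]
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dy.sum(axis=(0, 2, 3))
        dxhat = dy * g[None, :, None, None]
        if not train:
            return (dxhat * ivstd[None, :, None, None]).astype(_DT)
        # batch statistics participate in the graph
        t1 = dxhat
        t2 = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        t3 = xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return ((t1 - t2 - t3) * ivstd[None, :, None, None]).astype(_DT)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x).astype(_DT)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(_DT)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def __init__(self):
        super().__init__()
        self._y = None

    def forward(self, x, train=True):
        self._y = np.tanh(x).astype(_DT)
        return self._y

    def backward(self, dy):
        return (dy * (1.0 - self._y ** 2)).astype(_DT)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: Optional[np.random.Generator] = None):
        super().__init__()
        if not (0 <= p < 1):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()
        self._mask = None

    def forward(self, x, train=True):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return (x * self._mask).astype(_DT)

    def backward(self, dy):
        if self._mask is None:
            return dy
        return (dy * self._mask).astype(_DT)


class Adam:
    """Adam over a list of layers' parameter dicts."""

    def __init__(self, layers: List[Layer], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads.get(k)
                if g is None:
                    continue
                m = self.m[li][k]
                v = self.v[li][k]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
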