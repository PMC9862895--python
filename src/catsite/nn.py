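"""Minimal 3D conv-net building blocks on NumPy (float32, manual backprop).

Implements exactly what the ligandability classifier needs: 3D convolution
("same" padding, stride 1) via shifted BLAS matmuls, 2x max-pooling, batch
normalization, ReLU, dropout, dense layers, and softmax cross-entropy, plus
an Adam optimizer.  Layers cache what their backward pass needs; training
is deterministic given the RNG.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


def _offsets(k):
    return [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]


class Conv3d(Layer):
    """kxkxk convolution, stride 1, zero ("same") padding.

    Evaluated as k^3 shifted GEMMs over views of the padded volume -- no
    im2col materialization, which keeps both memory and gather cost low.
    """

    def __init__(self, in_ch, out_ch, k=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * k ** 3
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in),
                            size=(out_ch, in_ch, k, k, k)).astype(F32)
        self.b = np.zeros(out_ch, dtype=F32)
        self.k, self.in_ch, self.out_ch = k, in_ch, out_ch
        self.params, self.grads = [self.w, self.b], [None, None]

    @staticmethod
    def _pad(x, p):
        return np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3)

    @staticmethod
    def _shift_conv(xp, w_k, shape):
        """sum_k  w_k[(o, c)] @ view_k(xp)[(c, b*v)]  for all k^3 offsets."""
        b, _, d, h, w = shape
        k = w_k.shape[-1]
        out = None
        for (a, bb, cc) in _offsets(k):
            xs = xp[:, :, a:a + d, bb:bb + h, cc:cc + w]
            mat = xs.transpose(1, 0, 2, 3, 4).reshape(xs.shape[1], -1)
            term = w_k[:, :, a, bb, cc] @ mat
            out = term if out is None else out + term
        return out.reshape(-1, b, d * h * w).transpose(1, 0, 2)

    def forward(self, x, train=False, rng=None):
        x = x.astype(F32, copy=False)
        b, c, d, h, w = x.shape
        self._xp = self._pad(x, self.k // 2)
        out = self._shift_conv(self._xp, self.w, x.shape) \
            + self.b[None, :, None]
        return out.reshape(b, self.out_ch, d, h, w)

    def backward(self, dout):
        dout = dout.astype(F32, copy=False)
        b, _, d, h, w = dout.shape
        dflat = dout.reshape(b, self.out_ch, -1)
        dmat = dflat.transpose(1, 0, 2).reshape(self.out_ch, -1)  # (o, b*v)
        dw = np.empty_like(self.w)
        for (a, bb, cc) in _offsets(self.k):
            xs = self._xp[:, :, a:a + d, bb:bb + h, cc:cc + w]
            mat = xs.transpose(1, 0, 2, 3, 4).reshape(xs.shape[1], -1)
            dw[:, :, a, bb, cc] = dmat @ mat.T
        self.grads[0] = dw
        self.grads[1] = dflat.sum(axis=(0, 2)).astype(F32)
        self._xp = None
        # dx = correlation of dout with spatially flipped kernels
        w_back = self.w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        dp = self._pad(dout, self.k // 2)
        dx = self._shift_conv(dp, np.ascontiguousarray(w_back), dout.shape)
        return dx.reshape(b, self.in_ch, d, h, w)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2 (trailing odd voxels dropped)."""

    def forward(self, x, train=False, rng=None):
        b, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        xt = x[:, :, :d2 * 2, :h2 * 2, :w2 * 2]
        xr = xt.reshape(b, c, d2, 2, h2, 2, w2, 2)
        windows = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(b, c, d2, h2, w2, 8)
        self._argmax = windows.argmax(axis=-1)
        self._in_shape = x.shape
        return windows.max(axis=-1)

    def backward(self, dout):
        b, c, d, h, w = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dwin = np.zeros((b, c, d2, h2, w2, 8), dtype=F32)
        np.put_along_axis(dwin, self._argmax[..., None], dout[..., None], axis=-1)
        dxt = dwin.reshape(b, c, d2, h2, w2, 2, 2, 2) \
                  .transpose(0, 1, 2, 5, 3, 6, 4, 7) \
                  .reshape(b, c, d2 * 2, h2 * 2, w2 * 2)
        dx = np.zeros(self._in_shape, dtype=F32)
        dx[:, :, :d2 * 2, :h2 * 2, :w2 * 2] = dxt
        return dx


class BatchNorm(Layer):
    """Batch normalization over batch (and spatial dims when present)."""

    def __init__(self, n_ch, momentum=0.8, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(n_ch, dtype=F32)
        self.beta = np.zeros(n_ch, dtype=F32)
        self.running_mean = np.zeros(n_ch, dtype=F32)
        self.running_var = np.ones(n_ch, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self.params, self.grads = [self.gamma, self.beta], [None, None]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2, 3, 4)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1, 1, 1)

    def forward(self, x, train=False, rng=None):
        axes, shp = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(F32)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).reshape(shp)
        self._xhat = (x - mean.reshape(shp)) / self._std
        return (self.gamma.reshape(shp) * self._xhat
                + self.beta.reshape(shp)).astype(F32)

    def backward(self, dout):
        axes, shp = self._axes(dout), self._shape(dout)
        m = dout.size / dout.shape[1]
        self.grads[0] = (dout * self._xhat).sum(axis=axes).astype(F32)
        self.grads[1] = dout.sum(axis=axes).astype(F32)
        g = self.gamma.reshape(shp)
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=axes).reshape(shp)
              - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shp))
        return (dx / self._std).astype(F32)


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    def __init__(self, rate):
        super().__init__()
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(F32) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.params, self.grads = [self.w, self.b], [None, None]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0] = (self._x.T @ dout).astype(F32)
        self.grads[1] = dout.sum(axis=0).astype(F32)
        return (dout @ self.w.T).astype(F32)


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self):
        return [g for l in self.layers for g in l.grads]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def n_parameters(self):
        return int(sum(p.size for p in self.params))


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs, labels, eps=1e-12):
    """Mean negative log-likelihood of integer labels under `probs`."""
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


def softmax_ce_backward(probs, labels):
    """Gradient of mean cross-entropy wrt the logits."""
    d = probs.copy()
    d[np.arange(len(labels)), labels] -= 1.0
    return (d / len(labels)).astype(F32)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
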