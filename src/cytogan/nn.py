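"""Minimal layer-based neural-network framework on numpy.

Provides exactly the pieces the GAN and classifier modules need: 2-D
convolutions (im2col), dense layers, pooling/upsampling, the PGGAN
stabilizer layers (pixel norm, minibatch standard deviation, equalized
learning rate), softmax cross-entropy and an Adam optimizer.  All layers
implement explicit ``forward``/``backward`` passes; ``backward`` returns the
gradient with respect to the layer input, so gradients can be propagated
through a discriminator into a generator.

Everything is float32 and fully deterministic given a ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col helpers (NCHW layout)

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    hp, wp = x.shape[2], x.shape[3]
    oh = (hp - k) // stride + 1
    ow = (wp - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(n, c * k * k, oh * ow), (oh, ow, hp, wp)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int, geom):
    n, c, h, w = x_shape
    oh, ow, hp, wp = geom
    cols = cols.reshape(n, c, k, k, oh, ow)
    xg = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xg[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += cols[:, :, i, j]
    if pad:
        xg = xg[:, :, pad : pad + h, pad : pad + w]
    return xg


class Conv2d(Layer):
    """kxk convolution, stride 1, 'same' padding for odd k (or explicit pad).

    With ``equalized=True`` weights are stored as N(0,1) and rescaled at run
    time by the He constant, the equalized-learning-rate trick used by
    progressively grown GANs.
    """

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator,
                 pad: int | None = None, equalized: bool = False, gain: float = np.sqrt(2.0)):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        self.pad = (k // 2) if pad is None else pad
        self.equalized = equalized
        fan_in = in_ch * k * k
        self.scale = gain / np.sqrt(fan_in)
        if equalized:
            w = rng.standard_normal((out_ch, in_ch, k, k))
        else:
            w = rng.standard_normal((out_ch, in_ch, k, k)) * self.scale
        self.w = Param(w, "conv_w")
        self.b = Param(np.zeros(out_ch), "conv_b")

    def params(self):
        return [self.w, self.b]

    def _weight(self):
        return self.w.value * self.scale if self.equalized else self.w.value

    def forward(self, x, train=True):
        self._x_shape = x.shape
        cols, self._geom = _im2col(x, self.k, 1, self.pad)
        self._cols = cols
        wmat = self._weight().reshape(self.out_ch, -1)
        out = np.einsum("of,nfp->nop", wmat, cols, optimize=True)
        out += self.b.value[None, :, None]
        n = x.shape[0]
        oh, ow = self._geom[0], self._geom[1]
        return out.reshape(n, self.out_ch, oh, ow)

    def backward(self, grad):
        n, _, oh, ow = grad.shape
        g = grad.reshape(n, self.out_ch, oh * ow)
        wmat = self._weight().reshape(self.out_ch, -1)
        dw = np.einsum("nop,nfp->of", g, self._cols, optimize=True)
        if self.equalized:
            dw = dw * self.scale
        self.w.grad += dw.reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=(0, 2))
        dcols = np.einsum("of,nop->nfp", wmat, g, optimize=True)
        return _col2im(dcols, self._x_shape, self.k, 1, self.pad, self._geom)


class Dense(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator,
                 equalized: bool = False, gain: float = np.sqrt(2.0)):
        self.equalized = equalized
        self.scale = gain / np.sqrt(in_f)
        if equalized:
            w = rng.standard_normal((in_f, out_f))
        else:
            w = rng.standard_normal((in_f, out_f)) * self.scale
        self.w = Param(w, "dense_w")
        self.b = Param(np.zeros(out_f), "dense_b")

    def params(self):
        return [self.w, self.b]

    def _weight(self):
        return self.w.value * self.scale if self.equalized else self.w.value

    def forward(self, x, train=True):
        self._x = x
        return x @ self._weight() + self.b.value

    def backward(self, grad):
        dw = self._x.T @ grad
        if self.equalized:
            dw = dw * self.scale
        self.w.grad += dw
        self.b.grad += grad.sum(axis=0)
        return grad @ self._weight().T


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.alpha * grad)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Tanh(Layer):
    def forward(self, x, train=True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, *shape):
        self.shape = shape

    def forward(self, x, train=True):
        self._in = x.shape
        return x.reshape(x.shape[0], *self.shape)

    def backward(self, grad):
        return grad.reshape(self._in)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (input H, W must be even)."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        self._xr = xr
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only first max per window
        cum = np.cumsum(np.cumsum(self._mask, axis=3), axis=5)
        self._mask = self._mask & (cum == 1)
        return out

    def backward(self, grad):
        g = self._mask * grad[:, :, :, None, :, None]
        n, c, h2, _, w2, _ = g.shape
        return g.reshape(n, c, h2 * 2, w2 * 2)


class AvgPool2(Layer):
    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._shape
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return g


class UpsampleNearest2(Layer):
    def forward(self, x, train=True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class PixelNorm(Layer):
    """Per-pixel feature normalization used in PGGAN generators."""

    EPS = 1e-8

    def forward(self, x, train=True):
        self._x = x
        self._inv = 1.0 / np.sqrt((x**2).mean(axis=1, keepdims=True) + self.EPS)
        return x * self._inv

    def backward(self, grad):
        x, inv = self._x, self._inv
        c = x.shape[1]
        dot = (grad * x).mean(axis=1, keepdims=True)
        return inv * grad - (inv**3) * x * dot


class MinibatchStdDev(Layer):
    """Appends one channel holding the mean over-features batch std.

    The scalar s = mean_{c,h,w} sqrt(var_n(x) + eps) is broadcast as an extra
    feature map; its gradient flows back to every sample in the batch.
    """

    EPS = 1e-8

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        self._x = x
        mu = x.mean(axis=0, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=0)
        self._std = np.sqrt(var + self.EPS)  # (c,h,w)
        s = self._std.mean()
        feat = np.full((n, 1, h, w), s, dtype=x.dtype)
        return np.concatenate([x, feat], axis=1)

    def backward(self, grad):
        n, c1, h, w = grad.shape
        c = c1 - 1
        gmain = grad[:, :c]
        gs = grad[:, c].sum()  # d loss / d s
        x = self._x
        mu = x.mean(axis=0, keepdims=True)
        # ds/dx = (x - mu) / (n * std * C*H*W)
        dx = gs * (x - mu) / (n * self._std[None] * (c * h * w))
        return gmain + dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train=True):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# losses

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits)."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return float(loss), (d / n).astype(DTYPE)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def bce_with_logits(logits: np.ndarray, target: float):
    """Binary cross-entropy against a constant target in {0,1}; (loss, dlogits)."""
    p = sigmoid(logits)
    eps = 1e-12
    if target == 1:
        loss = -np.log(p + eps).mean()
    else:
        loss = -np.log(1.0 - p + eps).mean()
    d = (p - target) / logits.size
    return float(loss), d.astype(DTYPE)


# ---------------------------------------------------------------------------
# optimizer

class Adam:
    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def clip_params(params: list[Param], c: float) -> None:
    """WGAN weight clipping to [-c, c]."""
    for p in params:
        np.clip(p.value, -c, c, out=p.value)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f at x (test utility)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f(x)
        x[i] = old - eps
        fm = f(x)
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
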