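"""Small deterministic CPU engine for convolutional classifiers.

Implements exactly the layer vocabulary the blot classifiers need: same-size
2-D convolution (im2col + matmul), batch normalization, ReLU, max pooling,
dense layers, and softmax cross-entropy trained with Adam.  Float32
throughout, NCHW layout, every weight draw taken from a caller-supplied
``numpy`` generator so training is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "softmax",
    "train_network",
    "TrainingFailure",
]

_DT = np.float32


class TrainingFailure(RuntimeError):
    """Raised when the loss stops being finite."""


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[list[np.ndarray]]:
        """[param, grad] pairs; grads are rewritten in place by backward."""
        return []


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    n, c, hp, wp = xp.shape
    h, w = hp - k + 1, wp - k + 1
    cols = np.empty((n, c, k * k, h, w), dtype=xp.dtype)
    idx = 0
    for i in range(k):
        for j in range(k):
            cols[:, :, idx] = xp[:, :, i:i + h, j:j + w]
            idx += 1
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape: tuple[int, int, int, int], k: int) -> np.ndarray:
    n, c, hp, wp = shape
    h, w = hp - k + 1, wp - k + 1
    out = np.zeros(shape, dtype=cols.dtype)
    cols = cols.reshape(n, c, k * k, h, w)
    idx = 0
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + h, j:j + w] += cols[:, :, idx]
            idx += 1
    return out


class Conv2D(Layer):
    """Same-size convolution: odd kernel, stride 1, zero padding k//2.

    He-normal weight init from the supplied generator.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-size padding")
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.w = (rng.standard_normal((out_ch, in_ch * kernel * kernel))
                  * scale).astype(_DT)
        self.b = np.zeros(out_ch, dtype=_DT)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self.k = kernel
        self.in_ch = in_ch
        self._cache = None

    def forward(self, x, train):
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        cols = _im2col(xp, self.k)
        out = np.matmul(self.w[None], cols) + self.b[None, :, None]
        n, f, _ = out.shape
        self._cache = (cols, xp.shape, x.shape)
        return out.reshape(n, f, x.shape[2], x.shape[3])

    def backward(self, grad):
        cols, padded_shape, x_shape = self._cache
        n, f = grad.shape[:2]
        g = grad.reshape(n, f, -1)
        self.gw[...] = np.einsum("nfl,ncl->fc", g, cols, optimize=True)
        self.gb[...] = g.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T[None], g)
        dxp = _col2im(dcols, padded_shape, self.k)
        pad = self.k // 2
        if pad == 0:
            return dxp
        return dxp[:, :, pad:-pad, pad:-pad]

    def params(self):
        return [[self.w, self.gw], [self.b, self.gb]]


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics for eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_DT)
        self.beta = np.zeros(channels, dtype=_DT)
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels, dtype=_DT)
        self.run_var = np.ones(channels, dtype=_DT)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = ((1 - self.momentum) * self.run_mean
                             + self.momentum * mean).astype(_DT)
            self.run_var = ((1 - self.momentum) * self.run_var
                            + self.momentum * var).astype(_DT)
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, grad):
        xhat, inv, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.ggamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = grad.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        sum_gx = (grad * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        sum_g = grad.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        dx = (g * inv[None, :, None, None] / n_eff) * (
            n_eff * grad - sum_g - xhat * sum_gx
        )
        return dx.astype(_DT)

    def params(self):
        return [[self.gamma, self.ggamma], [self.beta, self.gbeta]]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool2D(Layer):
    """Non-overlapping max pooling; pool shape (ph, pw), trailing remainder
    rows/columns are dropped (floor semantics)."""

    def __init__(self, pool: tuple[int, int] = (2, 2)):
        self.ph, self.pw = pool

    def forward(self, x, train):
        n, c, h, w = x.shape
        ho, wo = h // self.ph, w // self.pw
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for {self.ph}x{self.pw} pool")
        xc = x[:, :, : ho * self.ph, : wo * self.pw]
        xr = xc.reshape(n, c, ho, self.ph, wo, self.pw)
        out = xr.max(axis=(3, 5))
        self._cache = (x.shape, xr, out)
        return out

    def backward(self, grad):
        x_shape, xr, out = self._cache
        mask = xr == out[:, :, :, None, :, None]
        # split ties evenly so gradient mass is conserved
        mask = mask / mask.sum(axis=(3, 5), keepdims=True)
        dxc = (mask * grad[:, :, :, None, :, None]).astype(_DT)
        n, c, h, w = x_shape
        ho, wo = h // self.ph, w // self.pw
        dx = np.zeros(x_shape, dtype=_DT)
        dx[:, :, : ho * self.ph, : wo * self.pw] = dxc.reshape(
            n, c, ho * self.ph, wo * self.pw
        )
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(_DT)
        self.b = np.zeros(n_out, dtype=_DT)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.gw[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.w.T

    def params(self):
        return [[self.w, self.gw], [self.b, self.gb]]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Network:
    """A plain layer stack ending in logits; softmax applied on demand."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def params(self) -> list[list[np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        probs = []
        for i in range(0, x.shape[0], batch_size):
            probs.append(softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(probs, axis=0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


class Adam:
    """Adaptive-moment optimizer (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[list[np.ndarray]], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps)


def train_network(
    net: Network,
    x: np.ndarray,
    y: np.ndarray,
    epochs: int,
    rng: np.random.Generator,
    batch_size: int = 16,
    lr: float = 1e-3,
) -> list[float]:
    """Minimize softmax cross-entropy; returns the mean loss per epoch.

    Shuffles with the supplied generator each epoch, so identical
    (network init, data, generator state) reproduce identical weights.
    Raises :class:`TrainingFailure` on a non-finite loss.
    """
    x = np.ascontiguousarray(x, dtype=_DT)
    y = np.asarray(y, dtype=np.int64)
    opt = Adam(net.params(), lr=lr)
    history: list[float] = []
    n = x.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            logits = net.forward(x[idx], train=True)
            probs = softmax(logits)
            eps = 1e-12
            loss = -np.log(probs[np.arange(idx.size), y[idx]] + eps).mean()
            if not np.isfinite(loss):
                raise TrainingFailure(f"non-finite loss at epoch {epoch}")
            grad = probs
            grad[np.arange(idx.size), y[idx]] -= 1.0
            net.backward((grad / idx.size).astype(_DT))
            opt.step()
            losses.append(float(loss))
        history.append(float(np.mean(losses)))
    return history
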