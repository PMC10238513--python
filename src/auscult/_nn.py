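"""Minimal NumPy neural-network layers with manual backpropagation.

Only what the auscultation classifier needs: 3x3 convolutions, batch
normalization, ReLU, 2x2 average pooling (ceil mode), dropout, pointwise
(per-time-step) linear layers, time smoothing, and a decoupled-weight-decay
Adam optimizer with a 1cycle learning-rate schedule.

Layers cache their forward inputs; calling ``backward`` immediately after the
matching ``forward`` propagates gradients and accumulates parameter gradients
in ``Param.grad``.  All arithmetic is float32.
"""

from __future__ import annotations

import math

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """3x3 same-padding convolution on (N, C, H, W), stride 1."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, kernel: int = 3):
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        self.pad = kernel // 2
        std = math.sqrt(2.0 / (in_ch * kernel * kernel))
        self.weight = Param(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)))
        self.bias = Param(np.zeros(out_ch))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xp = xp if training else None
        self._shape = x.shape
        n, _, h, w = x.shape
        acc = np.zeros((n, h, w, self.out_ch), dtype=np.float32)
        for di in range(self.k):
            for dj in range(self.k):
                xs = xp[:, :, di : di + h, dj : dj + w]
                # (N,H,W,O) += (N,C,H,W) x (O,C) contracted over C
                acc += np.tensordot(xs, self.weight.data[:, :, di, dj], axes=([1], [1]))
        y = acc.transpose(0, 3, 1, 2)
        y += self.bias.data[None, :, None, None]
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # with no cached input (inference-mode forward) only dx is computed,
        # which is what gradient-based receptive-field probes need
        xp, p = self._xp, self.pad
        n, _, h, w = self._shape
        dacc = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))  # (N,H,W,O)
        if xp is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dxp = np.zeros((dy.shape[0], self.in_ch, h + 2 * p, w + 2 * p), dtype=np.float32)
        for di in range(self.k):
            for dj in range(self.k):
                if xp is not None:
                    xs = xp[:, :, di : di + h, dj : dj + w]
                    self.weight.grad[:, :, di, dj] += np.tensordot(
                        dacc, xs, axes=([0, 1, 2], [0, 2, 3])
                    )
                dxs = np.tensordot(dacc, self.weight.data[:, :, di, dj], axes=([3], [0]))
                dxp[:, :, di : di + h, dj : dj + w] += dxs.transpose(0, 3, 1, 2)
        self._xp = None
        return np.ascontiguousarray(dxp[:, :, p : p + h, p : p + w])


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, C, ...) inputs.

    Each channel is standardized independently; in training mode batch
    statistics are used and running statistics updated, in inference mode the
    running statistics are used.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.c = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        return (1, self.c) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        bs = self._bshape(x.ndim)
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = x.size // self.c
            self.running_mean += self.momentum * (mu - self.running_mean)
            unbiased = var * (m / max(m - 1, 1))
            self.running_var += self.momentum * (unbiased - self.running_var)
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu.reshape(bs)) * inv_std.reshape(bs)
            self._cache = (xhat, inv_std, m)
        else:
            inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(bs)) * inv_std.reshape(bs)
            self._cache = (None, inv_std, None)
        return (self.gamma.data.reshape(bs) * xhat + self.beta.data.reshape(bs)).astype(
            np.float32
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._cache
        axes = (0,) + tuple(range(2, dy.ndim))
        bs = self._bshape(dy.ndim)
        if xhat is None:  # inference-mode backward (e.g. receptive-field probes)
            return dy * (self.gamma.data * inv_std).reshape(bs)
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        g = self.gamma.data.reshape(bs)
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=axes).reshape(bs)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes).reshape(bs)
        dx = inv_std.reshape(bs) * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class AvgPool2x2(Layer):
    """2x2 average pooling with ceil-mode output and edge cells averaged over
    the available inputs only (so a trailing odd row/column is not biased
    toward zero)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = -(-h // 2), -(-w // 2)
        xp = np.zeros((n, c, 2 * ho, 2 * wo), dtype=np.float32)
        xp[:, :, :h, :w] = x
        s = xp.reshape(n, c, ho, 2, wo, 2).sum(axis=(3, 5))
        ch = np.full(ho, 2.0, dtype=np.float32)
        cw = np.full(wo, 2.0, dtype=np.float32)
        if h % 2:
            ch[-1] = 1.0
        if w % 2:
            cw[-1] = 1.0
        count = ch[:, None] * cw[None, :]
        self._cache = (x.shape, count)
        return s / count[None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, c, h, w), count = self._cache
        g = dy / count[None, None]
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3)
        return np.ascontiguousarray(gx[:, :, :h, :w])


class FreqMean(Layer):
    """Average the frequency axis away: (N, C, F, T) -> (N, C, T)."""

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._f = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, :, None, :] / self._f, self._f, axis=2)


class TimeSmooth(Layer):
    """Sum of average and max pooling (size 3, stride 1, pad 1) over time.

    Input (N, C, T); output the same shape.
    """

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, t = x.shape
        xa = np.zeros((n, c, t + 2), dtype=np.float32)
        xa[:, :, 1:-1] = x
        avg = (xa[:, :, :-2] + xa[:, :, 1:-1] + xa[:, :, 2:]) / 3.0
        xm = np.full((n, c, t + 2), -np.inf, dtype=np.float32)
        xm[:, :, 1:-1] = x
        stack = np.stack([xm[:, :, :-2], xm[:, :, 1:-1], xm[:, :, 2:]])
        arg = stack.argmax(axis=0)
        self._cache = (x.shape, arg)
        return avg + stack.max(axis=0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (n, c, t), arg = self._cache
        dxp = np.zeros((n, c, t + 2), dtype=np.float32)
        third = dy / 3.0
        for o in range(3):
            dxp[:, :, o : o + t] += third
            dxp[:, :, o : o + t] += np.where(arg == o, dy, 0.0)
        return np.ascontiguousarray(dxp[:, :, 1:-1])


class PointwiseLinear(Layer):
    """A fully connected layer applied independently at every time step:
    (N, C, T) -> (N, O, T)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((out_ch, in_ch))
        else:
            std = math.sqrt(2.0 / in_ch)
            w = rng.normal(0.0, std, size=(out_ch, in_ch))
        self.weight = Param(w)
        self.bias = Param(np.zeros(out_ch))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        y = np.tensordot(x, self.weight.data, axes=([1], [1]))  # (N,T,O)
        y += self.bias.data[None, None, :]
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._x is not None:
            self.bias.grad += dy.sum(axis=(0, 2))
            self.weight.grad += np.tensordot(dy, self._x, axes=([0, 2], [0, 2]))
            self._x = None
        dx = np.tensordot(dy, self.weight.data, axes=([1], [0]))  # (N,T,C)
        return np.ascontiguousarray(np.moveaxis(dx, 2, 1))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad * p.grad - v)
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= lr * (update + self.weight_decay * p.data)


def one_cycle_lr(
    step: int,
    total_steps: int,
    max_lr: float,
    pct_start: float = 0.3,
    div_factor: float = 25.0,
    final_div_factor: float = 1e4,
) -> float:
    """1cycle schedule: cosine warm-up from ``max_lr/div_factor`` to ``max_lr``
    over the first ``pct_start`` of training, then cosine annealing down to
    ``initial/final_div_factor``."""
    if not 0 <= step < total_steps:
        raise ValueError(f"step {step} outside schedule of {total_steps} steps")
    initial = max_lr / div_factor
    min_lr = initial / final_div_factor
    up_steps = max(1, int(round(pct_start * total_steps)))
    if step < up_steps:
        frac = step / max(up_steps - 1, 1)
        return initial + (max_lr - initial) * 0.5 * (1.0 - math.cos(math.pi * frac))
    frac = (step - up_steps) / max(total_steps - up_steps - 1, 1)
    return min_lr + (max_lr - min_lr) * 0.5 * (1.0 + math.cos(math.pi * frac))
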