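"""Compact CPU neural-network engine (numpy).

The networks used here are small — three convolutions, batch norm, average
pooling and single affine heads — so the package carries its own minimal
layer engine instead of a deep-learning framework dependency.  Every layer
implements an explicit functional pair::

    y, cache = layer.forward(x, train=...)
    gx = layer.backward(gy, cache)      # accumulates parameter grads

``forward`` may be called several times before ``backward`` (the shared
feature extractor runs once per domain batch); each call returns its own
cache, so backward passes can be replayed per input. All gradients are
verified against central finite differences in the test suite.

Shapes follow the (batch, maps, height, width) convention; EEG trials enter
as (batch, 1, channels, T).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Conv2d", "BatchNorm2d", "ReLU", "AvgPool1xK",
           "Dropout2d", "Flatten", "Linear", "Sequential", "GradReverse",
           "grad_reverse", "softmax", "Adam"]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False):
        raise NotImplementedError

    def backward(self, gy: np.ndarray, cache):
        raise NotImplementedError


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                    fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Layer):
    """Stride-1 2-D convolution (cross-correlation) with optional
    width-only zero padding — covers both the length-preserving temporal
    convolutions (kernel 1 x k, pad k//2) and the spatial collapse
    (kernel ch x 1, no pad)."""

    def __init__(self, in_maps: int, out_maps: int, kh: int, kw: int,
                 pad_w: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_maps * kh * kw
        self.weight = Param(_fan_in_uniform(rng, (out_maps, in_maps, kh, kw),
                                            fan_in))
        self.bias = Param(_fan_in_uniform(rng, (out_maps,), fan_in))
        self.kh, self.kw, self.pad_w = kh, kw, pad_w

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def _cols(self, xp: np.ndarray) -> np.ndarray:
        """Contiguous im2col matrix (B, C*kh*kw, Ho*Wo)."""
        B, C, H, W = xp.shape
        ho, wo = H - self.kh + 1, W - self.kw + 1
        s = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, (B, C, self.kh, self.kw, ho, wo),
            (s[0], s[1], s[2], s[3], s[2], s[3]))
        return np.ascontiguousarray(view).reshape(
            B, C * self.kh * self.kw, ho * wo)

    def forward(self, x: np.ndarray, train: bool = False):
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (0, 0), (self.pad_w, self.pad_w)))
        cols = self._cols(xp)
        F = self.weight.value.shape[0]
        w2d = self.weight.value.reshape(F, -1)
        ho, wo = H - self.kh + 1, W + 2 * self.pad_w - self.kw + 1
        y = (w2d @ cols).reshape(B, F, ho, wo)
        y += self.bias.value[None, :, None, None]
        return y, (cols, xp.shape)

    def backward(self, gy: np.ndarray, cache):
        cols, xp_shape = cache
        B, F, ho, wo = gy.shape
        gy2d = gy.reshape(B, F, ho * wo)
        w2d = self.weight.value.reshape(F, -1)
        self.weight.grad += (
            (gy2d @ cols.transpose(0, 2, 1)).sum(axis=0)
            .reshape(self.weight.value.shape))
        self.bias.grad += gy.sum(axis=(0, 2, 3))
        gcols = (w2d.T @ gy2d).reshape(
            B, xp_shape[1], self.kh, self.kw, ho, wo)
        gxp = np.zeros(xp_shape)
        for i in range(self.kh):
            for j in range(self.kw):
                gxp[:, :, i:i + ho, j:j + wo] += gcols[:, :, i, j]
        if self.pad_w:
            return gxp[:, :, :, self.pad_w:-self.pad_w]
        return gxp


class BatchNorm2d(Layer):
    """Per-feature-map batch normalisation; batch statistics in training,
    exponentially tracked running statistics in eval."""

    def __init__(self, n_maps: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_maps))
        self.beta = Param(np.zeros(n_maps))
        self.running_mean = np.zeros(n_maps)
        self.running_var = np.ones(n_maps)
        self.momentum, self.eps = momentum, eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False):
        axes = (0, 2, 3)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
        y = (self.gamma.value[None, :, None, None] * xhat
             + self.beta.value[None, :, None, None])
        return y, (xhat, std, train)

    def backward(self, gy: np.ndarray, cache):
        xhat, std, train = cache
        axes = (0, 2, 3)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = self.gamma.value[None, :, None, None]
        if not train:
            return gy * g / std[None, :, None, None]
        gxhat = gy * g
        mean_g = gxhat.mean(axis=axes, keepdims=True)
        mean_gx = (gxhat * xhat).mean(axis=axes, keepdims=True)
        return (gxhat - mean_g - xhat * mean_gx) / std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False):
        mask = x > 0
        return x * mask, mask

    def backward(self, gy: np.ndarray, cache):
        return gy * cache


class AvgPool1xK(Layer):
    """Average pooling with a (1, k) window and stride k; the temporal
    length must be divisible by k (guaranteed by the config invariants)."""

    def __init__(self, k: int):
        self.k = k

    def forward(self, x: np.ndarray, train: bool = False):
        B, C, H, W = x.shape
        if W % self.k:
            raise ValueError(f"width {W} not divisible by pool size {self.k}")
        y = x.reshape(B, C, H, W // self.k, self.k).mean(axis=-1)
        return y, x.shape

    def backward(self, gy: np.ndarray, cache):
        return np.repeat(gy, self.k, axis=-1) / self.k


class Dropout2d(Layer):
    """Channel-wise dropout: whole feature maps are zeroed with
    probability p during training (inverted scaling)."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool = False):
        if not train or self.p == 0.0:
            return x, None
        if self.rng is None:
            raise RuntimeError("Dropout2d needs .rng set for training")
        keep = self.rng.random((x.shape[0], x.shape[1], 1, 1)) >= self.p
        scale = keep / (1.0 - self.p)
        return x * scale, scale

    def backward(self, gy: np.ndarray, cache):
        if cache is None:
            return gy
        return gy * cache


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, gy: np.ndarray, cache):
        return gy.reshape(cache)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Param(_fan_in_uniform(rng, (n_in, n_out), n_in))
        self.bias = Param(_fan_in_uniform(rng, (n_out,), n_in))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False):
        return x @ self.weight.value + self.bias.value, x

    def backward(self, gy: np.ndarray, cache):
        x = cache
        self.weight.grad += x.T @ gy
        self.bias.grad += gy.sum(axis=0)
        return gy @ self.weight.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False):
        caches = []
        for layer in self.layers:
            x, c = layer.forward(x, train=train)
            caches.append(c)
        return x, caches

    def backward(self, gy: np.ndarray, caches):
        for layer, c in zip(reversed(self.layers), reversed(caches)):
            gy = layer.backward(gy, c)
        return gy


class GradReverse(Layer):
    """Gradient reversal: identity forward, gradient negation backward.

    Placed between the shared feature extractor and each domain
    discriminator, it turns the discriminator's minimisation into
    adversarial feature confusion.
    """

    def forward(self, x: np.ndarray, train: bool = False):
        return x, None

    def backward(self, gy: np.ndarray, cache):
        return -gy


def grad_reverse(x: np.ndarray) -> np.ndarray:
    """Forward view of the gradient-reversal operation (the identity); the
    backward contract lives in :class:`GradReverse`."""
    return np.asarray(x)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimiser over a list of :class:`Param`."""

    def __init__(self, params: list[Param], lr: float = 3e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
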