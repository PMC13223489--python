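"""Reverse-mode layers for the desk-scale CNN engine.

Arrays are NHWC float32.  Convolutions use TensorFlow-style "same" padding
(asymmetric: the extra pixel, if any, goes on the bottom/right), which is
what reproduces the 128 -> 64 -> 32 -> 16 shape chain of the two-branch
extractor.  Each layer caches what its backward pass needs; `backward`
returns one gradient per input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "Layer",
    "Conv2D",
    "DepthwiseConv2D",
    "Pool2D",
    "BatchNorm",
    "Concat",
    "Flatten",
    "GlobalAvgPool",
    "Dense",
    "Dropout",
    "Activation",
    "SigmoidOutput",
]


# ---------------------------------------------------------------------------
# activations: name -> (f, df_from_x_and_y)

def _relu(x):
    return np.maximum(x, 0.0)


def _d_relu(x, y):
    return (x > 0).astype(x.dtype)


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _d_elu(x, y):
    return np.where(x > 0, 1.0, y + 1.0).astype(x.dtype)


def _tanh(x):
    return np.tanh(x)


def _d_tanh(x, y):
    return 1.0 - y * y


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _swish(x):
    return x * _sigmoid(x)


def _d_swish(x, y):
    s = _sigmoid(x)
    return s + x * s * (1.0 - s)


def _softplus(x):
    return np.logaddexp(0.0, x)


def _d_softplus(x, y):
    return _sigmoid(x)


ACTIVATIONS = {
    "relu": (_relu, _d_relu),
    "elu": (_elu, _d_elu),
    "tanh": (_tanh, _d_tanh),
    "swish": (_swish, _d_swish),
    "softplus": (_softplus, _d_softplus),
}


def _same_pad(size: int, kernel: int, stride: int) -> tuple[int, int, int]:
    """(out_size, pad_before, pad_after) for TF-style same padding."""
    out = -(-size // stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return out, before, total - before


class Layer:
    """Base layer: named, possibly trainable, with cached backward state."""

    def __init__(self, name: str):
        self.name = name
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.trainable = True

    def init_params(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        return None

    def forward(self, xs, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, stride: int):
    """Patches of a padded NHWC tensor: (N, Ho, Wo, k, k, C)."""
    n, h, w, c = x.shape
    ho, pt, pb = _same_pad(h, k, stride)
    wo, pl, pr = _same_pad(w, k, stride)
    xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    # win: (N, Hp-k+1, Wp-k+1, C, k, k) -> subsample by stride, reorder
    cols = win[:, ::stride, ::stride]
    cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3))
    return cols, (ho, wo, pt, pb, pl, pr)


def _col2im(grad_cols, x_shape, k, stride, pads):
    """Scatter-add patch gradients back to the unpadded input."""
    n, h, w, c = x_shape
    ho, wo, pt, pb, pl, pr = pads
    hp, wp = h + pt + pb, w + pl + pr
    gx = np.zeros((n, hp, wp, c), dtype=grad_cols.dtype)
    for i in range(k):
        for j in range(k):
            gx[:, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                grad_cols[:, :, :, i, j, :]
            )
    return gx[:, pt : pt + h, pl : pl + w]


class Conv2D(Layer):
    def __init__(self, name, filters, kernel=3, stride=1, activation=None):
        super().__init__(name)
        self.filters = int(filters)
        self.kernel = int(kernel)
        self.stride = int(stride)
        self.activation = activation
        self._in_channels = None

    def build(self, in_channels: int):
        self._in_channels = int(in_channels)

    def init_params(self, rng):
        k, m, nf = self.kernel, self._in_channels, self.filters
        scale = np.sqrt(2.0 / (k * k * m))  # He init, suits relu-family
        self.params["W"] = (rng.standard_normal((k * k * m, nf)) * scale).astype(
            np.float32
        )
        self.params["b"] = np.zeros(nf, dtype=np.float32)

    def forward(self, xs, training=False):
        (x,) = xs
        cols, pads = _im2col(x, self.kernel, self.stride)
        n, ho, wo = cols.shape[:3]
        flat = cols.reshape(n * ho * wo, -1)
        z = flat @ self.params["W"] + self.params["b"]
        z = z.reshape(n, ho, wo, self.filters)
        self._cache = (x.shape, flat, pads, z if self.activation else None)
        if self.activation:
            f, _ = ACTIVATIONS[self.activation]
            out = f(z)
            self._cache = (x.shape, flat, pads, (z, out))
            return out
        return z

    def backward(self, grad):
        x_shape, flat, pads, act_cache = self._cache
        if self.activation:
            z, y = act_cache
            _, df = ACTIVATIONS[self.activation]
            grad = grad * df(z, y)
        n, ho, wo, nf = grad.shape
        gflat = grad.reshape(n * ho * wo, nf)
        self.grads["W"] = flat.T @ gflat
        self.grads["b"] = gflat.sum(axis=0)
        gcols = (gflat @ self.params["W"].T).reshape(
            n, ho, wo, self.kernel, self.kernel, -1
        )
        return [_col2im(gcols, x_shape, self.kernel, self.stride, pads)]


class DepthwiseConv2D(Layer):
    """Per-channel k x k convolution (the depthwise half of a separable conv)."""

    def __init__(self, name, kernel=3, stride=1, activation=None):
        super().__init__(name)
        self.kernel = int(kernel)
        self.stride = int(stride)
        self.activation = activation
        self._in_channels = None

    def build(self, in_channels: int):
        self._in_channels = int(in_channels)

    def init_params(self, rng):
        k, m = self.kernel, self._in_channels
        scale = np.sqrt(2.0 / (k * k))
        self.params["W"] = (rng.standard_normal((k, k, m)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(m, dtype=np.float32)

    def forward(self, xs, training=False):
        (x,) = xs
        cols, pads = _im2col(x, self.kernel, self.stride)  # (N,Ho,Wo,k,k,C)
        z = np.einsum("nhwijc,ijc->nhwc", cols, self.params["W"]) + self.params["b"]
        self._cache = (x.shape, cols, pads, None)
        if self.activation:
            f, _ = ACTIVATIONS[self.activation]
            out = f(z)
            self._cache = (x.shape, cols, pads, (z, out))
            return out
        return z

    def backward(self, grad):
        x_shape, cols, pads, act_cache = self._cache
        if self.activation:
            z, y = act_cache
            _, df = ACTIVATIONS[self.activation]
            grad = grad * df(z, y)
        self.grads["W"] = np.einsum("nhwijc,nhwc->ijc", cols, grad)
        self.grads["b"] = grad.sum(axis=(0, 1, 2))
        gcols = grad[:, :, :, None, None, :] * self.params["W"][None, None, None]
        return [_col2im(gcols, x_shape, self.kernel, self.stride, pads)]


class Pool2D(Layer):
    """Max or average pooling with same padding."""

    def __init__(self, name, pool=2, stride=None, mode="max"):
        super().__init__(name)
        self.pool = int(pool)
        self.stride = int(stride) if stride is not None else int(pool)
        if mode not in ("max", "avg"):
            raise ValueError(f"unknown pool mode {mode!r}")
        self.mode = mode
        self.trainable = False

    def forward(self, xs, training=False):
        (x,) = xs
        if self.mode == "max":
            fill = np.float32(-np.inf)
        else:
            fill = np.float32(0.0)
        n, h, w, c = x.shape
        ho, pt, pb = _same_pad(h, self.pool, self.stride)
        wo, pl, pr = _same_pad(w, self.pool, self.stride)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=fill)
        win = np.lib.stride_tricks.sliding_window_view(
            xp, (self.pool, self.pool), axis=(1, 2)
        )[:, :: self.stride, :: self.stride]  # (N,Ho,Wo,C,p,p)
        if self.mode == "max":
            out = win.max(axis=(4, 5))
            mask = win == out[..., None, None]
            # split ties evenly so the gradient check stays symmetric
            mask = mask / mask.sum(axis=(4, 5), keepdims=True)
            self._cache = (x.shape, (ho, wo, pt, pb, pl, pr), mask)
        else:
            out = win.mean(axis=(4, 5))
            self._cache = (x.shape, (ho, wo, pt, pb, pl, pr), None)
        return np.ascontiguousarray(out)

    def backward(self, grad):
        x_shape, pads, mask = self._cache
        p = self.pool
        if self.mode == "max":
            g = grad[..., None, None] * mask  # (N,Ho,Wo,C,p,p)
        else:
            g = np.broadcast_to(
                grad[..., None, None] / (p * p), grad.shape + (p, p)
            )
        gcols = np.ascontiguousarray(g.transpose(0, 1, 2, 4, 5, 3))
        return [_col2im(gcols, x_shape, p, self.stride, pads)]


class BatchNorm(Layer):
    """Channel-wise batch normalization (spatial or dense input)."""

    def __init__(self, name, momentum=0.9, eps=1e-5):
        super().__init__(name)
        self.momentum = momentum
        self.eps = eps
        self._channels = None

    def build(self, channels: int):
        self._channels = int(channels)

    def init_params(self, rng):
        c = self._channels
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, xs, training=False):
        (x,) = xs
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if self.trainable:
                m = self.momentum
                self.running_mean = m * self.running_mean + (1 - m) * mean
                self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, training)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, grad):
        xhat, inv, axes, training = self._cache
        self.grads["gamma"] = (grad * xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self.params["gamma"]
        if not training:
            return [g * inv]
        m = np.prod([xhat.shape[a] for a in axes])
        gx = (
            g - g.mean(axis=axes) - xhat * (g * xhat).sum(axis=axes) / m
        ) * inv
        return [gx]


class Concat(Layer):
    """Channel-axis concatenation of the branch outputs."""

    def __init__(self, name):
        super().__init__(name)
        self.trainable = False

    def forward(self, xs, training=False):
        self._splits = np.cumsum([x.shape[-1] for x in xs])[:-1]
        return np.concatenate(xs, axis=-1)

    def backward(self, grad):
        return np.split(grad, self._splits, axis=-1)


class Flatten(Layer):
    def __init__(self, name):
        super().__init__(name)
        self.trainable = False

    def forward(self, xs, training=False):
        (x,) = xs
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return [grad.reshape(self._shape)]


class GlobalAvgPool(Layer):
    def __init__(self, name):
        super().__init__(name)
        self.trainable = False

    def forward(self, xs, training=False):
        (x,) = xs
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        g = np.broadcast_to(grad[:, None, None, :] / (h * w), self._shape)
        return [np.ascontiguousarray(g)]


class Dense(Layer):
    def __init__(self, name, units):
        super().__init__(name)
        self.units = int(units)
        self._in_features = None

    def build(self, in_features: int):
        self._in_features = int(in_features)

    def init_params(self, rng):
        m, n = self._in_features, self.units
        scale = np.sqrt(2.0 / m)
        self.params["W"] = (rng.standard_normal((m, n)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(n, dtype=np.float32)

    def forward(self, xs, training=False):
        (x,) = xs
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return [grad @ self.params["W"].T]


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, name, rate):
        super().__init__(name)
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.trainable = False
        self.rng = np.random.default_rng(0)

    def forward(self, xs, training=False):
        (x,) = xs
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return [grad]
        return [grad * self._mask]


class Activation(Layer):
    def __init__(self, name, fn):
        super().__init__(name)
        if fn not in ACTIVATIONS:
            raise ValueError(f"unknown activation {fn!r}; choose from {sorted(ACTIVATIONS)}")
        self.fn = fn
        self.trainable = False

    def forward(self, xs, training=False):
        (x,) = xs
        f, _ = ACTIVATIONS[self.fn]
        y = f(x)
        self._cache = (x, y)
        return y

    def backward(self, grad):
        x, y = self._cache
        _, df = ACTIVATIONS[self.fn]
        return [grad * df(x, y)]


class SigmoidOutput(Layer):
    """Single-unit dense layer with sigmoid, the fixed classification output."""

    def __init__(self, name):
        super().__init__(name)
        self._in_features = None

    def build(self, in_features: int):
        self._in_features = int(in_features)

    def init_params(self, rng):
        m = self._in_features
        scale = np.sqrt(1.0 / m)
        self.params["W"] = (rng.standard_normal((m, 1)) * scale).astype(np.float32)
        self.params["b"] = np.zeros(1, dtype=np.float32)

    def forward(self, xs, training=False):
        (x,) = xs
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        p = _sigmoid(z)
        self._p = p
        return p[:, 0]

    def backward(self, grad):
        # grad arrives w.r.t. the probability p
        gz = (grad[:, None] if grad.ndim == 1 else grad) * self._p * (1.0 - self._p)
        self.grads["W"] = self._x.T @ gz
        self.grads["b"] = gz.sum(axis=0)
        return [gz @ self.params["W"].T]

    def backward_from_bce(self, y_true, n):
        """Gradient of mean BCE w.r.t. pre-sigmoid logit: (p - y)/n."""
        gz = (self._p[:, 0] - y_true)[:, None] / n
        self.grads["W"] = self._x.T @ gz
        self.grads["b"] = gz.sum(axis=0)
        return [gz @ self.params["W"].T]
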