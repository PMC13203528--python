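"""Minimal numpy layer framework with explicit forward/backward passes.

Only what the dual-frame fall classifier needs: 1-D depthwise and pointwise
convolutions (bias-free), batch/group normalization, SiLU, max pooling,
dropout, squeeze-and-excitation, and linear layers.  Every layer caches what
its backward pass needs during ``forward``; ``backward`` takes the gradient
of the loss with respect to the layer output, accumulates parameter
gradients, and returns the gradient with respect to the input.  Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "DepthwiseConv1d",
    "PointwiseConv1d",
    "BatchNorm1d",
    "GroupNorm",
    "SiLU",
    "MaxPool1d",
    "Dropout",
    "SEBlock",
    "Linear",
    "GlobalAvgPool1d",
    "RngBox",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size


class RngBox:
    """Shared mutable RNG handle so dropout masks reseed with the model."""

    def __init__(self, seed: int = 0):
        self.rng = np.random.default_rng(seed)

    def seed(self, seed: int) -> None:
        self.rng = np.random.default_rng(seed)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal -------------------------------------------------------
    def children(self):
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        # blocks may hold the same layer both as an attribute and inside a
        # Sequential, so deduplicate by identity while preserving order
        out: list[Parameter] = []
        seen: set[int] = set()

        def collect(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    collect(item)

        collect(self)
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def cast(self, dtype) -> "Module":
        """Cast all parameters, gradients and normalization buffers.

        Training in float32 roughly halves wall time on bandwidth-bound
        CPUs; gradient-verification tests keep the float64 default.
        """
        for p in self.parameters():
            p.data = p.data.astype(dtype)
            p.grad = p.grad.astype(dtype)
        stack = [self]
        seen = set()
        while stack:
            m = stack.pop()
            if id(m) in seen:
                continue
            seen.add(id(m))
            for v in vars(m).values():
                if isinstance(v, Module):
                    stack.append(v)
                elif isinstance(v, (list, tuple)):
                    stack.extend(i for i in v if isinstance(i, Module))
            if isinstance(m, BatchNorm1d):
                m.running_mean = m.running_mean.astype(dtype)
                m.running_var = m.running_var.astype(dtype)
        return self

    # -- interface -------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _kaiming_uniform(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator):
    bound = math.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class DepthwiseConv1d(Module):
    """Per-channel temporal convolution, bias-free.

    ``padding`` is an explicit (left, right) pair: symmetric "same" padding
    for the feature-extraction blocks, left-only ``(k - 1) * d`` padding for
    causal TCN layers (output cropped on the right by construction).
    Input/output shape ``(B, C, T)``.
    """

    def __init__(
        self,
        channels: int,
        kernel_size: int,
        dilation: int = 1,
        padding: tuple[int, int] = (0, 0),
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.kernel_size = kernel_size
        self.dilation = dilation
        self.padding = padding
        self.weight = Parameter(_kaiming_uniform((channels, kernel_size), kernel_size, rng))
        self._cache = None

    def forward(self, x):
        left, right = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
        span = (self.kernel_size - 1) * self.dilation + 1
        t_out = xp.shape[2] - span + 1
        w = self.weight.data
        out = xp[:, :, :t_out] * w[:, 0, None]
        for j in range(1, self.kernel_size):
            off = j * self.dilation
            out += xp[:, :, off : off + t_out] * w[:, j, None]
        self._cache = (xp, x.shape, t_out)
        return out

    def backward(self, grad):
        xp, x_shape, t_out = self._cache
        w = self.weight.data
        dxp = np.zeros_like(xp)
        for j in range(self.kernel_size):
            off = j * self.dilation
            sl = xp[:, :, off : off + t_out]
            self.weight.grad[:, j] += (sl * grad).sum(axis=(0, 2))
            dxp[:, :, off : off + t_out] += grad * w[:, j, None]
        left = self.padding[0]
        return dxp[:, :, left : left + x_shape[2]]


class PointwiseConv1d(Module):
    """1x1 channel-mixing convolution, bias-free.  Shape ``(B, Cin, T)`` ->
    ``(B, Cout, T)``."""

    def __init__(self, in_channels: int, out_channels: int, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming_uniform((out_channels, in_channels), in_channels, rng))
        self._x = None

    def forward(self, x):
        self._x = x
        return np.matmul(self.weight.data, x)

    def backward(self, grad):
        self.weight.grad += np.tensordot(grad, self._x, axes=([0, 2], [0, 2]))
        return np.matmul(self.weight.data.T, grad)


class BatchNorm1d(Module):
    """Batch normalization over (batch, time) per channel.

    Accepts ``(B, C, T)`` or ``(B, C)`` input.  Running statistics use
    momentum 0.1 with the unbiased variance, matching the common deep
    learning convention; normalization uses the biased batch variance.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def _axes_shape(self, x):
        if x.ndim == 3:
            return (0, 2), (1, -1, 1)
        return (0,), (1, -1)

    def forward(self, x):
        axes, shape = self._axes_shape(x)
        g = self.gamma.data.reshape(shape)
        b = self.beta.data.reshape(shape)
        if self.training:
            mean = x.mean(axis=axes)
            xc = x - mean.reshape(shape)
            var = np.mean(xc * xc, axis=axes)
            n = x.size // x.shape[1]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = xc * inv.reshape(shape)
            self._cache = (xhat, inv, axes, shape, n)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean.reshape(shape)) * inv.reshape(shape)
            self._cache = (xhat, inv, axes, shape, None)
        return g * xhat + b

    def backward(self, grad):
        xhat, inv, axes, shape, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.data.reshape(shape)
        if n is None:  # eval mode: running stats are constants
            return grad * g * inv.reshape(shape)
        dxhat = grad * g
        mean_d = dxhat.mean(axis=axes).reshape(shape)
        mean_dx = (dxhat * xhat).mean(axis=axes).reshape(shape)
        return inv.reshape(shape) * (dxhat - mean_d - xhat * mean_dx)


class GroupNorm(Module):
    """Per-sample group normalization over ``(B, C, T)`` with affine scale."""

    def __init__(self, channels: int, groups: int, eps: float = 1e-5):
        super().__init__()
        if channels % groups != 0:
            raise ValueError("channels must be divisible by groups")
        self.groups = groups
        self.eps = eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._cache = None

    def forward(self, x):
        B, C, T = x.shape
        G = self.groups
        xg = x.reshape(B, G, C // G * T)
        mean = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mean) * inv).reshape(B, C, T)
        self._cache = (xhat, inv, (B, C, T))
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, grad):
        xhat, inv, (B, C, T) = self._cache
        G = self.groups
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        dxhat = (grad * self.gamma.data[None, :, None]).reshape(B, G, C // G * T)
        xh = xhat.reshape(B, G, C // G * T)
        mean_d = dxhat.mean(axis=2, keepdims=True)
        mean_dx = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = inv * (dxhat - mean_d - xh * mean_dx)
        return dx.reshape(B, C, T)


class SiLU(Module):
    def forward(self, x):
        from scipy.special import expit

        s = expit(x)
        self._cache = (x, s)
        return x * s

    def backward(self, grad):
        x, s = self._cache
        return grad * s * (1.0 + x * (1.0 - s))


class MaxPool1d(Module):
    """Kernel-2 stride-2 max pooling with floor semantics (odd tails dropped)."""

    def __init__(self, kernel_size: int = 2, stride: int = 2):
        super().__init__()
        if kernel_size != 2 or stride != 2:
            raise NotImplementedError("only kernel=stride=2 is supported")
        self._cache = None

    def forward(self, x):
        B, C, T = x.shape
        t_out = T // 2
        xr = x[:, :, : 2 * t_out].reshape(B, C, t_out, 2)
        idx = xr.argmax(axis=3)
        self._cache = (idx, x.shape, t_out)
        return np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]

    def backward(self, grad):
        idx, x_shape, t_out = self._cache
        B, C, T = x_shape
        dxr = np.zeros((B, C, t_out, 2))
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=3)
        dx = np.zeros(x_shape)
        dx[:, :, : 2 * t_out] = dxr.reshape(B, C, 2 * t_out)
        return dx


class Dropout(Module):
    """Inverted dropout drawing masks from a shared seeded generator."""

    def __init__(self, p: float, rng_box: RngBox):
        super().__init__()
        self.p = p
        self.rng_box = rng_box
        self._mask = None

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng_box.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class SEBlock(Module):
    """Squeeze-and-excitation channel attention for ``(B, C, T)`` features.

    Global average pooling over time yields a channel descriptor; a
    bottleneck MLP (hidden width ``max(floor(C / r), 1)``, ReLU inner,
    sigmoid outer) produces per-channel weights in (0, 1) that rescale the
    input features.
    """

    def __init__(self, channels: int, reduction: int, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(channels // reduction, 1)
        self.w1 = Parameter(_kaiming_uniform((hidden, channels), channels, rng))
        self.w2 = Parameter(_kaiming_uniform((channels, hidden), hidden, rng))
        self.bias = bias
        if bias:
            self.b1 = Parameter(np.zeros(hidden))
            self.b2 = Parameter(np.zeros(channels))
        self._cache = None

    def forward(self, x):
        z = x.mean(axis=2)
        pre1 = z @ self.w1.data.T + (self.b1.data if self.bias else 0.0)
        h = np.maximum(pre1, 0.0)
        pre2 = h @ self.w2.data.T + (self.b2.data if self.bias else 0.0)
        s = 1.0 / (1.0 + np.exp(-pre2))
        self._cache = (x, z, pre1, h, s)
        return x * s[:, :, None]

    def backward(self, grad):
        x, z, pre1, h, s = self._cache
        dx_direct = grad * s[:, :, None]
        ds = (grad * x).sum(axis=2)
        dpre2 = ds * s * (1.0 - s)
        self.w2.grad += dpre2.T @ h
        if self.bias:
            self.b2.grad += dpre2.sum(axis=0)
        dh = dpre2 @ self.w2.data
        dpre1 = dh * (pre1 > 0)
        self.w1.grad += dpre1.T @ z
        if self.bias:
            self.b1.grad += dpre1.sum(axis=0)
        dz = dpre1 @ self.w1.data
        return dx_direct + dz[:, :, None] / x.shape[2]


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_kaiming_uniform((out_features, in_features), in_features, rng))
        self.use_bias = bias
        if bias:
            self.b = Parameter(np.zeros(out_features))
        self._x = None

    def forward(self, x):
        self._x = x
        out = x @ self.weight.data.T
        if self.use_bias:
            out = out + self.b.data
        return out

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.use_bias:
            self.b.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class GlobalAvgPool1d(Module):
    """Mean over the time axis: ``(B, C, T)`` -> ``(B, C)``."""

    def forward(self, x):
        self._t = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None] / self._t, self._t, axis=2)
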