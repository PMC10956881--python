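"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the segmentation network needs: 2-D convolution (im2col + GEMM),
stride-2 transpose convolution, group normalization, ReLU, a sequential
container and SGD with momentum. All arithmetic is float32; every layer
caches its forward activations only while ``training`` is True, so
inference over large inputs stays memory-light.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "GroupNorm",
    "ReLU",
    "Sequential",
    "SGD",
]


class Parameter:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: parameter discovery, train/eval mode, grad reset."""

    def __init__(self):
        self.training = True

    # -- parameter / submodule walking -------------------------------------
    def _children(self):
        for name, obj in vars(self).items():
            if isinstance(obj, Module):
                yield name, obj
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, obj in vars(self).items():
            if isinstance(obj, Parameter):
                yield (prefix + name, obj)
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self):
        self.training = True
        for _, child in self._children():
            child.train()
        return self

    def eval(self):
        self.training = False
        for _, child in self._children():
            child.eval()
        return self

    # -- state (checkpointing) ---------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float32)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.value.shape}")
            p.value[...] = arr

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args):
        return self.forward(*args)


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, C*kh*kw, Ho*Wo) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c = x.shape[:2]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col` (scatter-add patches back)."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols6 = cols.reshape(b, c, kh, kw, ho, wo)
    xpad = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for a in range(kh):
        for bb in range(kw):
            xpad[:, :, a : a + stride * ho : stride, bb : bb + stride * wo : stride] += cols6[:, :, a, bb]
    return xpad[:, :, pad : pad + h, pad : pad + w]


def _out_hw(h: int, w: int, k: int, stride: int, pad: int):
    return (h + 2 * pad - k) // stride + 1, (w + 2 * pad - k) // stride + 1


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_out = c_out * kernel * kernel
        std = np.sqrt(2.0 / fan_out)  # He init, fan-out mode
        self.weight = Parameter(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self._cache = None

    def forward(self, x):
        if x.shape[1] != self.c_in:
            raise ValueError(f"Conv2d expected {self.c_in} input channels, got {x.shape[1]}")
        cols, ho, wo = _im2col(x, self.kernel, self.kernel, self.stride, self.pad)
        wmat = self.weight.value.reshape(self.c_out, -1)
        y = np.matmul(wmat, cols)
        if self.bias is not None:
            y += self.bias.value[:, None]
        if self.training:
            self._cache = (x.shape, cols)
        return y.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, dy):
        x_shape, cols = self._cache
        b = dy.shape[0]
        dyf = dy.reshape(b, self.c_out, -1)
        wmat = self.weight.value.reshape(self.c_out, -1)
        self.weight.grad += np.einsum("bol,bil->oi", dyf, cols, optimize=True).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dcols = np.matmul(wmat.T, dyf)
        self._cache = None
        return _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, self.pad)

    def macs(self, h: int, w: int):
        ho, wo = _out_hw(h, w, self.kernel, self.stride, self.pad)
        return self.c_out * ho * wo * self.c_in * self.kernel * self.kernel, (ho, wo)


class ConvTranspose2d(Module):
    """Transpose convolution with kernel == stride (non-overlapping upsampling)."""

    def __init__(self, c_in: int, c_out: int, kernel: int = 2, *, rng: np.random.Generator):
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_out = c_out * kernel * kernel
        std = np.sqrt(2.0 / fan_out)
        self.weight = Parameter(rng.normal(0.0, std, (c_in, c_out, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self._cache = None

    def forward(self, x):
        if x.shape[1] != self.c_in:
            raise ValueError(f"ConvTranspose2d expected {self.c_in} input channels, got {x.shape[1]}")
        b, _, h, w = x.shape
        k = self.kernel
        y6 = np.einsum("bcij,cdpq->bdipjq", x, self.weight.value, optimize=True)
        y = y6.reshape(b, self.c_out, h * k, w * k) + self.bias.value[None, :, None, None]
        if self.training:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        b, _, h, w = x.shape
        k = self.kernel
        dy6 = dy.reshape(b, self.c_out, h, k, w, k)
        self.weight.grad += np.einsum("bcij,bdipjq->cdpq", x, dy6, optimize=True)
        self.bias.grad += dy.sum(axis=(0, 2, 3))
        self._cache = None
        return np.einsum("bdipjq,cdpq->bcij", dy6, self.weight.value, optimize=True)

    def macs(self, h: int, w: int):
        k = self.kernel
        return self.c_in * h * w * self.c_out * k * k, (h * k, w * k)


class GroupNorm(Module):
    """Per-sample normalization over channel groups; batch-size independent."""

    def __init__(self, channels: int, groups: int = 32, eps: float = 1e-5):
        super().__init__()
        groups = min(groups, channels)
        while channels % groups:
            groups -= 1
        self.channels, self.groups, self.eps = channels, groups, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._cache = None

    def forward(self, x):
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(b, c, h, w)
        y = xhat * self.gamma.value[None, :, None, None] + self.beta.value[None, :, None, None]
        if self.training:
            self._cache = (xhat, inv, (b, c, h, w))
        return y

    def backward(self, dy):
        xhat, inv, (b, c, h, w) = self._cache
        g = self.groups
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.value[None, :, None, None]).reshape(b, g, -1)
        xhat_g = xhat.reshape(b, g, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xhat_g).mean(axis=2, keepdims=True)
        dx = inv * (dxhat - m1 - xhat_g * m2)
        self._cache = None
        return dx.reshape(b, c, h, w)

    def macs(self, h: int, w: int):
        return 0, (h, w)


class ReLU(Module):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x):
        y = np.maximum(x, 0.0)
        if self.training:
            self._mask = x > 0
        return y

    def backward(self, dy):
        dx = dy * self._mask
        self._mask = None
        return dx

    def macs(self, h: int, w: int):
        return 0, (h, w)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def macs(self, h: int, w: int):
        total = 0
        for layer in self.layers:
            m, (h, w) = layer.macs(h, w)
            total += m
        return total, (h, w)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class SGD:
    """Momentum SGD with decoupled-from-nothing L2 weight decay (classic form)."""

    def __init__(self, params, lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        if lr < 0:
            raise ValueError("learning rate must be non-negative")
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._velocity = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            v *= self.momentum
            v += g
            p.value -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
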