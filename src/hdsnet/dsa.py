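"""Dynamic Sparse Attention (DSA).

External attention over a flattened bottleneck feature map: two learnable,
sample-independent memory units K and V share the (C, S) shape of the
flattened map (S = H·W tokens). The attention score is formed *element-wise*
(Q ⊙ K, no matrix product), normalized by a softmax over the token axis,
multiplied by a random Bernoulli 0/1 mask whose keep-probability ``p`` (the
"sparsity ratio") controls how much attention mass survives, and finally
multiplied element-wise with V. The block wraps this between two 1×1
convolutions with a flatten/unflatten in between, so its output shape equals
its input shape.

At train time a fresh mask is drawn every forward pass; at eval time the
mask is replaced by its expectation (every entry = p), dropout-style, so
inference is deterministic. With p = 1 the masked path is numerically
identical to plain external attention; with p = 0 the attended feature is
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Conv2d, Module, Parameter

__all__ = [
    "FlatFeature",
    "MemoryUnits",
    "sample_bernoulli_mask",
    "flatten_feature",
    "unflatten_feature",
    "softmax_tokens",
    "dsa_attend",
    "DSABlock",
]


@dataclass
class FlatFeature:
    """A (B, C, S) view of a feature map plus the spatial dims to invert it."""

    values: np.ndarray
    height: int
    width: int

    def __post_init__(self):
        if self.values.ndim != 3:
            raise ValueError("FlatFeature values must be (batch, channels, tokens)")
        if self.values.shape[2] != self.height * self.width:
            raise ValueError(
                f"token count {self.values.shape[2]} != height*width = {self.height * self.width}"
            )


@dataclass
class MemoryUnits:
    """Learnable external memory K, V, each shaped like one flattened map (C, S)."""

    K: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        if self.K.shape != self.V.shape or self.K.ndim != 2:
            raise ValueError("K and V must both be 2-D (channels, tokens) of equal shape")


def flatten_feature(x: np.ndarray) -> FlatFeature:
    b, c, h, w = x.shape
    return FlatFeature(x.reshape(b, c, h * w), h, w)


def unflatten_feature(f: FlatFeature) -> np.ndarray:
    b, c, _ = f.values.shape
    return f.values.reshape(b, c, f.height, f.width)


def sample_bernoulli_mask(shape, p: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. Bernoulli(p) 0/1 mask; exactly all-ones at p=1 and all-zeros at p=0."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"keep-probability p must lie in [0, 1], got {p}")
    shape = tuple(int(s) for s in (shape if np.iterable(shape) else (shape,)))
    if len(shape) == 0 or any(s <= 0 for s in shape):
        raise ValueError(f"mask shape must have positive extents, got {shape}")
    if p == 1.0:
        return np.ones(shape, dtype=np.float32)
    if p == 0.0:
        return np.zeros(shape, dtype=np.float32)
    return (rng.random(shape) < p).astype(np.float32)


def softmax_tokens(scores: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last (token) axis."""
    shifted = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def dsa_attend(f_in: FlatFeature, mem: MemoryUnits, mask: np.ndarray) -> FlatFeature:
    """Masked element-wise external attention on a flat feature.

    M = Q ⊙ K; α = softmax(M over tokens) ⊙ mask; out = α ⊙ V.
    ``mask`` may be (C, S) (shared across the batch) or (B, C, S).
    """
    q = f_in.values
    b, c, s = q.shape
    if mem.K.shape != (c, s):
        raise ValueError(f"memory units shaped {mem.K.shape}, feature is ({c}, {s})")
    if mask.shape not in ((c, s), (b, c, s)):
        raise ValueError(f"mask shaped {mask.shape} incompatible with feature ({b}, {c}, {s})")
    if not np.isfinite(q).all():
        raise FloatingPointError("non-finite values in DSA input feature")
    m = q * mem.K[None]
    alpha = softmax_tokens(m) * mask
    out = alpha * mem.V[None]
    return FlatFeature(out, f_in.height, f_in.width)


class DSABlock(Module):
    """1×1 conv → flatten → masked element-wise external attention → unflatten → 1×1 conv.

    Parameters
    ----------
    channels : bottleneck channel count C (input == output).
    height, width : the spatial dims the block is configured for; the memory
        units are (C, height·width) so any other input resolution is rejected.
    p : Bernoulli keep-probability ("sparsity ratio"), default 0.9.
    rng : generator used for weight init and for drawing train-time masks.
    """

    def __init__(self, channels: int, height: int, width: int, p: float = 0.9,
                 *, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"sparse ratio p must lie in [0, 1], got {p}")
        self.channels, self.height, self.width, self.p = channels, height, width, p
        s = height * width
        self.conv_in = Conv2d(channels, channels, 1, rng=rng)
        # external memory units K ("F1*") and V ("F2*"), plus element-wise
        # learnable scalings standing in for their linear maps L
        self.K = Parameter(rng.normal(0.0, 0.02, (channels, s)))
        self.V = Parameter(rng.normal(0.0, 0.02, (channels, s)))
        self.scale_k = Parameter(np.ones((channels, s)))
        self.scale_v = Parameter(np.ones((channels, s)))
        self.conv_out = Conv2d(channels, channels, 1, rng=rng)
        self.rng = rng
        self._cache = None

    def set_rng(self, rng: np.random.Generator):
        self.rng = rng

    def _check(self, x):
        b, c, h, w = x.shape
        if c != self.channels or (h, w) != (self.height, self.width):
            raise ValueError(
                f"DSA block is configured for {self.channels}×{self.height}×{self.width} "
                f"features but received {c}×{h}×{w}; rebuild the model with an input size "
                f"whose stride-16 map matches the memory-unit token count"
            )

    def forward(self, x):
        self._check(x)
        b, c, h, w = x.shape
        s = h * w
        q4 = self.conv_in(x)
        q = q4.reshape(b, c, s)
        if not np.isfinite(q).all():
            raise FloatingPointError("non-finite values entering DSA attention")
        if self.training:
            mask = sample_bernoulli_mask((b, c, s), self.p, self.rng)
        else:
            mask = np.full((1, 1, 1), self.p, dtype=np.float32)  # expectation mask
        keff = self.K.value * self.scale_k.value
        veff = self.V.value * self.scale_v.value
        m = q * keff[None]
        alpha = softmax_tokens(m)
        alpha_masked = alpha * mask
        out = alpha_masked * veff[None]
        if self.training:
            self._cache = (q, mask, alpha, alpha_masked)
        y = self.conv_out(out.reshape(b, c, h, w))
        return y

    def backward(self, dy):
        q, mask, alpha, alpha_masked = self._cache
        b, c, s = q.shape
        keff = self.K.value * self.scale_k.value
        veff = self.V.value * self.scale_v.value
        dout = self.conv_out.backward(dy).reshape(b, c, s)
        # out = alpha_masked ⊙ veff
        dveff = (dout * alpha_masked).sum(axis=0)
        self.V.grad += dveff * self.scale_v.value
        self.scale_v.grad += dveff * self.V.value
        dalpha = dout * veff[None] * mask
        # softmax backward over token axis
        dm = alpha * (dalpha - (dalpha * alpha).sum(axis=-1, keepdims=True))
        dkeff = (dm * q).sum(axis=0)
        self.K.grad += dkeff * self.scale_k.value
        self.scale_k.grad += dkeff * self.K.value
        dq = dm * keff[None]
        self._cache = None
        return self.conv_in.backward(dq.reshape(b, c, self.height, self.width))

    def macs(self, h: int, w: int):
        m1, _ = self.conv_in.macs(h, w)
        m2, _ = self.conv_out.macs(h, w)
        # element-wise attention multiplies: Q⊙K, α⊙mask, α⊙V (+ the two scalings)
        attn = 5 * self.channels * h * w
        return m1 + m2 + attn, (h, w)
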