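"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; calling :meth:`Tensor.backward` on a scalar result accumulates
gradients into every upstream tensor created with ``requires_grad=True``.
The op set is the minimum needed for the colorization networks: elementwise
arithmetic with broadcasting, exp/log/tanh/sigmoid/relu/abs/pow, reductions,
2-D matmul, strided 2-D convolution (im2col), nearest-neighbour upsampling
and channel concatenation. Everything is computed in float64: training at
desk scale is cheap and gradient checks against central finite differences
stay well conditioned.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "upsample_nearest2d",
    "batch_norm_2d",
    "set_default_dtype",
    "get_default_dtype",
]

# float64 by default so finite-difference gradient checks are well
# conditioned; the training loop switches to float32, which halves memory
# traffic and roughly doubles BLAS throughput at desk scale.
_DEFAULT_DTYPE = np.float64


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DEFAULT_DTYPE


def _as_array(data) -> np.ndarray:
    return np.asarray(data, dtype=_DEFAULT_DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.reshape(())[()])

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self**-1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        data = self.data**e

        def backward(g):
            if self.requires_grad:
                self._accum(g * e * self.data ** (e - 1.0))

        return Tensor._make(data, (self,), backward)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._make(data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - data * data))

        return Tensor._make(data, (self,), backward)

    def sigmoid(self):
        data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.abs(self.data))),
            np.exp(-np.abs(self.data)) / (1.0 + np.exp(-np.abs(self.data))),
        )

        def backward(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def abs(self):
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return Tensor._make(np.abs(self.data), (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through the interior, zero outside."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                axes = (axis,) if np.isscalar(axis) else tuple(axis)
                axes = tuple(a % self.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            count = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ------------------------------------------------------------ shape & algebra
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def matmul(self, other: "Tensor"):
        other = Tensor._coerce(other)
        data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        return Tensor._make(data, (self, other), backward)

    __matmul__ = matmul


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tensors, backward)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, im2col implementation.

    x: (N, C, H, W); w: (O, C, kh, kw); b: (O,) or None.
    """
    n, c, h, wdt = x.shape
    o, cin, kh, kw = w.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    s = int(stride)
    p = int(padding)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (h + 2 * p - kh) // s + 1
    wo = (wdt + 2 * p - kw) // s + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::s, ::s]  # (N, C, ho, wo, kh, kw)
    cols = np.ascontiguousarray(windows.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * kh * kw, ho * wo
    )
    w2 = w.data.reshape(o, c * kh * kw)
    out = np.matmul(w2, cols).reshape(n, o, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, o, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gr = g.reshape(n, o, ho * wo)
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", gr, cols).reshape(w.shape)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(gr.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.matmul(w2.T, gr).reshape(n, c, kh, kw, ho, wo)
            gxp = np.zeros((n, c, h + 2 * p, wdt + 2 * p), dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += gcols[
                        :, :, i, j
                    ]
            x._accum(gxp[:, :, p : p + h, p : p + wdt] if p else gxp)

    return Tensor._make(out, parents, backward)


def batch_norm_2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    mean: np.ndarray,
    var: np.ndarray,
    eps: float,
    batch_stats: bool,
) -> Tensor:
    """Fused 2-D batch normalization with hand-written backward.

    ``mean``/``var`` are (1, C, 1, 1) arrays. With ``batch_stats`` they are
    the current batch's own statistics (gradient flows through them);
    otherwise they are treated as constants (population/eval mode).
    """
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * inv_std
    out = xhat * gamma.data + beta.data
    axes = (0, 2, 3)
    count = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes, keepdims=True))
        if x.requires_grad:
            if batch_stats:
                g_mean = g.mean(axis=axes, keepdims=True)
                gx_mean = (g * xhat).mean(axis=axes, keepdims=True)
                dx = (gamma.data * inv_std) * (g - g_mean - xhat * gx_mean)
            else:
                dx = g * gamma.data * inv_std
            x._accum(dx)

    return Tensor._make(out, (x, gamma, beta), backward)


def upsample_nearest2d(x: Tensor, factor: int) -> Tensor:
    f = int(factor)
    n, c, h, w = x.shape
    data = x.data.repeat(f, axis=2).repeat(f, axis=3)

    def backward(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))

    return Tensor._make(data, (x,), backward)
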