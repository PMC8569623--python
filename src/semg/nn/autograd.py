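"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
``ndarray`` and records a backward closure. Only the operations the
gesture-recognition network needs are implemented (elementwise arithmetic
with broadcasting, matmul, activations, reductions, reshapes, concatenation,
grouped 2-D convolution, softmax cross-entropy). Gradients are accumulated
into ``.grad`` by :meth:`Tensor.backward` in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "conv2d", "softmax_cross_entropy", "concatenate"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = tuple(_prev)

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            # copy: the incoming buffer may be shared with another consumer
            self.grad = np.array(grad, dtype=np.float64)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: sequences unroll deep graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                              self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                               other.data.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- activations -------------------------------------------------------

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * y * (1.0 - y))

        out._backward = bwd
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - y * y))

        out._backward = bwd
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bwd
        return out

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bwd
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._backward = bwd
        return out


class Parameter(Tensor):
    """A trainable tensor (always requires gradient)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out._backward = bwd
    return out


# -- grouped 2-D convolution ----------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride, pad):
    """[B,C,H,W] -> [B, C, kh, kw, Ho, Wo] view-derived column array."""
    sh, sw = stride
    ph, pw = pad
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::sh, ::sw, :, :]            # [B,C,Ho,Wo,kh,kw]
    return np.ascontiguousarray(windows.transpose(0, 1, 4, 5, 2, 3)), x.shape


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), padding=(0, 0), groups: int = 1) -> Tensor:
    """Grouped 2-D cross-correlation.

    x: [B, Cin, H, W]; w: [Cout, Cin/groups, kh, kw]; b: [Cout] or None.
    Cin and Cout must be divisible by ``groups``.
    """
    B, Cin, H, W = x.data.shape
    Cout, Cin_g, kh, kw = w.data.shape
    if Cin % groups or Cout % groups:
        raise ValueError(f"channels ({Cin}->{Cout}) not divisible by groups={groups}")
    if Cin_g != Cin // groups:
        raise ValueError(f"weight expects {Cin_g} in-channels/group, got {Cin // groups}")
    sh, sw = stride
    ph, pw = padding
    Ho = (H + 2 * ph - kh) // sh + 1
    Wo = (W + 2 * pw - kw) // sw + 1

    cols, padded_shape = _im2col(x.data, kh, kw, (sh, sw), (ph, pw))
    # [B, g, Cin_g*kh*kw, Ho*Wo]
    cols_g = cols.reshape(B, groups, Cin_g * kh * kw, Ho * Wo)
    w_g = w.data.reshape(groups, Cout // groups, Cin_g * kh * kw)
    y = np.matmul(w_g[None], cols_g)             # [B, g, Cout/g, Ho*Wo]
    y = y.reshape(B, Cout, Ho, Wo)
    if b is not None:
        y = y + b.data.reshape(1, Cout, 1, 1)

    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y, any(t.requires_grad for t in prev), prev)

    def bwd(g):
        g_ = g.reshape(B, groups, Cout // groups, Ho * Wo)
        if w.requires_grad:
            dw = np.matmul(g_, np.swapaxes(cols_g, -1, -2)).sum(axis=0)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(np.swapaxes(w_g, -1, -2)[None], g_)
            dcols = dcols.reshape(B, Cin, kh, kw, Ho, Wo)
            dxp = np.zeros((B, Cin, padded_shape[2], padded_shape[3]))
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += dcols[:, :, i, j]
            dx = dxp[:, :, ph:ph + H, pw:pw + W] if (ph or pw) else dxp
            x._accumulate(dx)

    out._backward = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray):
    """Mean cross-entropy over a batch; returns (loss Tensor, probs ndarray)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    probs = e / e.sum(axis=1, keepdims=True)
    B = logits.data.shape[0]
    nll = -np.log(probs[np.arange(B), labels] + 1e-300)
    out = Tensor(nll.mean(), logits.requires_grad, (logits,))

    def bwd(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(B), labels] -= 1.0
            logits._accumulate(g * d / B)

    out._backward = bwd
    return out, probs
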