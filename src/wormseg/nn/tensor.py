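"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network code in :mod:`wormseg.model` needs 2-D convolutions, transposed
convolutions, matrix products, reductions and elementwise nonlinearities with
gradients.  This module provides exactly that: a :class:`Tensor` wrapping an
``ndarray`` plus a tape of primitive operations, each with a hand-written
vector-Jacobian product.  Everything runs on the CPU (float32 by default,
switchable) and is fully deterministic.  Gradients of every primitive are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concatenate", "no_grad", "is_grad_enabled",
           "set_default_dtype", "get_default_dtype"]

_GRAD_ENABLED = True
_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Set the floating dtype new tensors are created with.

    float32 (the default) is fast enough for training; the
    finite-difference gradient tests switch to float64.
    """
    global _DTYPE
    _DTYPE = np.dtype(dtype).type


def get_default_dtype():
    return _DTYPE


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- basic properties -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- autograd -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None  # free references

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g
        else:
            self.grad = self.grad + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise ----------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sqrt(self):
        return self**0.5

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        # plain python float: a numpy float64 scalar would promote the
        # whole backward pass to float64 under NEP-50 rules
        c = float(np.sqrt(2.0 / np.pi))
        x = self.data
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out_data = 0.5 * x * (1.0 + t)

        def backward(g):
            if self.requires_grad:
                dinner = c * (1.0 + 3 * 0.044715 * x**2)
                d = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t**2) * dinner
                self._accum(g * d)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                shape = [
                    1 if i in axes else s for i, s in enumerate(self.data.shape)
                ]
                g = g.reshape(shape)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- softmax / norm helpers ----------------------------------------------
    def softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                gs = (g * out_data).sum(axis=axis, keepdims=True)
                self._accum(out_data * (g - gs))

        return Tensor._make(out_data, (self,), backward)

    def log_softmax(self, axis=-1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        sm = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out_data, (self,), backward)

    # -- convolution primitives ----------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" | None = None,
               stride: int = 1, padding: int = 0):
        """2-D cross-correlation: x (B,Cin,H,W) * w (Cout,Cin,kh,kw)."""
        out_data = _conv_forward(self.data, weight.data, stride, padding)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None, None]
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            if self.requires_grad:
                self._accum(
                    _conv_backward_input(
                        g, weight.data, self.data.shape, stride, padding
                    )
                )
            if weight.requires_grad:
                weight._accum(
                    _conv_backward_weight(self.data, g, weight.data.shape,
                                          stride, padding)
                )
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        return Tensor._make(out_data, parents, backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor" | None = None,
                         stride: int = 1, padding: int = 0):
        """Transposed convolution: x (B,Cin,H,W), w (Cin,Cout,kh,kw).

        Forward pass is the adjoint of :meth:`conv2d`, so output spatial size
        is ``(H-1)*stride - 2*padding + k``.
        """
        cin, cout, kh, kw = weight.data.shape
        b, _, h, w = self.data.shape
        out_shape = (
            b,
            cout,
            (h - 1) * stride - 2 * padding + kh,
            (w - 1) * stride - 2 * padding + kw,
        )
        # conv_transpose forward == conv backward-input with w viewed as
        # (Cin=Cout_of_conv, Cout, kh, kw)
        out_data = _conv_backward_input(self.data, weight.data, out_shape,
                                        stride, padding)
        if bias is not None:
            out_data = out_data + bias.data[None, :, None, None]
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            if self.requires_grad:
                self._accum(_conv_forward(g, weight.data, stride, padding))
            if weight.requires_grad:
                weight._accum(
                    _conv_backward_weight(g, self.data, weight.data.shape,
                                          stride, padding)
                )
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))

        return Tensor._make(out_data, parents, backward)


def concatenate(tensors, axis=0):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# raw conv kernels (numpy, no autograd)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    # (B, C, Ho, Wo, kh, kw)
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))
    return np.ascontiguousarray(win[:, :, ::stride, ::stride])


def _conv_forward(x, w, stride, padding):
    cout, cin, kh, kw = w.shape
    cols = _im2col(x, kh, kw, stride, padding)  # B,C,Ho,Wo,kh,kw
    b, _, ho, wo = cols.shape[:4]
    cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, cin * kh * kw)
    out = cols2 @ w.reshape(cout, -1).T
    return out.reshape(b, ho, wo, cout).transpose(0, 3, 1, 2)


def _conv_backward_weight(x, gout, wshape, stride, padding):
    cout, cin, kh, kw = wshape
    cols = _im2col(x, kh, kw, stride, padding)
    b, _, ho, wo = cols.shape[:4]
    cols2 = cols.transpose(0, 2, 3, 1, 4, 5).reshape(b * ho * wo, cin * kh * kw)
    g2 = gout.transpose(0, 2, 3, 1).reshape(b * ho * wo, cout)
    return (g2.T @ cols2).reshape(wshape)


def _conv_backward_input(gout, w, xshape, stride, padding):
    cout, cin, kh, kw = w.shape
    b, _, h, wd = xshape
    ho, wo = gout.shape[2], gout.shape[3]
    gx_p = np.zeros((b, cin, h + 2 * padding, wd + 2 * padding), dtype=gout.dtype)
    g2 = gout.transpose(0, 2, 3, 1).reshape(b * ho * wo, cout)
    cols = (g2 @ w.reshape(cout, -1)).reshape(b, ho, wo, cin, kh, kw)
    cols = cols.transpose(0, 3, 1, 2, 4, 5)  # B,C,Ho,Wo,kh,kw
    for i in range(kh):
        for j in range(kw):
            gx_p[:, :, i : i + stride * ho : stride,
                 j : j + stride * wo : stride] += cols[:, :, :, :, i, j]
    if padding:
        gx_p = gx_p[:, :, padding:-padding, padding:-padding]
    return gx_p
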