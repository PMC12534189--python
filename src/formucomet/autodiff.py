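"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough tensor calculus for a small set transformer: broadcasting
elementwise arithmetic, (batched) matmul, softmax, layer normalization,
relu, stable log-sigmoid, reductions, concatenation and integer-array
gather.  Values are float32 by default; gradients are accumulated in
the value dtype.

Usage: wrap leaves in :class:`Tensor` (``requires_grad=True`` for
parameters and attribution inputs), compose ops, call ``backward()`` on
a scalar result, read ``.grad`` off the leaves.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple[np.ndarray | None, ...]] | None = None

    # -- graph construction -----------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = parents if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data - other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)),
        )

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data**2), other.shape),
            ),
        )

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __pow__(self, p: float):
        return Tensor._make(
            self.data**p, (self,), lambda g: (g * p * self.data ** (p - 1),)
        )

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = self.data @ other.data

        def backward(g):
            # 2-D weight on the right: flatten the batch into one GEMM
            # instead of materializing per-batch outer products.
            if other.data.ndim == 2 and self.data.ndim >= 2:
                ga = g @ other.data.T
                gb = (
                    self.data.reshape(-1, self.data.shape[-1]).T
                    @ g.reshape(-1, g.shape[-1])
                )
                return ga, gb
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(out, (self, other), backward)

    # -- nonlinearities ----------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def log_sigmoid(self):
        """Numerically stable log(sigmoid(x)) = -softplus(-x)."""
        x = self.data
        out = np.minimum(x, 0.0) - np.log1p(np.exp(-np.abs(x)))
        sig = np.exp(out)  # sigmoid(x), computed without overflow
        return Tensor._make(out.astype(DTYPE), (self,), lambda g: (g * (1.0 - sig),))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    # -- reductions / shaping ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(np.asarray(out, dtype=DTYPE), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(*axes), (self,), lambda g: (g.transpose(*inv),)
        )

    def gather(self, index: np.ndarray, axis: int = 0):
        """Take rows along ``axis`` by integer array (with repeats)."""
        index = np.asarray(index)
        out = np.take(self.data, index, axis=axis)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(np.moveaxis(full, axis, 0), index, np.moveaxis(g, axis, 0))
            return (full,)

        return Tensor._make(out, (self,), backward)

    def slice_axis1(self, start: int, stop: int):
        """Static slice along axis 1 (token axis)."""
        out = self.data[:, start:stop]

        def backward(g):
            full = np.zeros_like(self.data)
            full[:, start:stop] = g
            return (full,)

        return Tensor._make(out, (self,), backward)

    # -- structured ops ----------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (out * (g - dot),)

        return Tensor._make(out, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Normalize over the last axis, then scale and shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = xhat * gamma.data + beta.data
        d = self.data.shape[-1]

        def backward(g):
            gx_hat = g * gamma.data
            gx = inv * (
                gx_hat
                - gx_hat.mean(axis=-1, keepdims=True)
                - xhat * (gx_hat * xhat).mean(axis=-1, keepdims=True)
            )
            ggamma = _unbroadcast(g * xhat, gamma.shape)
            gbeta = _unbroadcast(g, beta.shape)
            return gx, ggamma, gbeta

        return Tensor._make(out.astype(DTYPE), (self, gamma, beta), backward)

    # -- autodiff -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=DTYPE)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if p._backward is None:  # leaf
                    p.grad = pg if p.grad is None else p.grad + pg
                else:
                    key = id(p)
                    grads[key] = pg if key not in grads else grads[key] + pg


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(datas))
        )

    return Tensor._make(out, tuple(tensors), backward)
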