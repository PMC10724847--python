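"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the package's neural components need:
dense affine maps, rectifier/logistic nonlinearities, row gather/scatter
(segment sums over graph incidence lists), concatenation, and stable
binary-cross-entropy / squared-error reductions.  Gradients are accumulated
by topological-order backpropagation over a dynamically built tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "matmul",
    "add",
    "sub",
    "mul",
    "relu",
    "sigmoid",
    "softplus",
    "gather_rows",
    "segment_sum",
    "hstack",
    "sum_all",
    "bce_with_logits",
    "mse",
]


class Tensor:
    """Node in the computation graph: a value, an optional gradient, and
    the closure that routes incoming gradient to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this node (default seed gradient: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # Convenience operators (constants are promoted).
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __radd__ = __add__
    __rmul__ = __mul__


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(data) -> Tensor:
    return Tensor(data)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(-_unbroadcast(g, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0.0)

    def backward(g):
        x._accumulate(g * mask)

    return Tensor(out_data, (x,), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = _sigmoid(x.data)

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return Tensor(s, (x,), backward)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), computed stably; gradient is the logistic function."""
    out_data = np.logaddexp(0.0, x.data)

    def backward(g):
        x._accumulate(g * _sigmoid(x.data))

    return Tensor(out_data, (x,), backward)


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows x[idx]; gradient scatter-adds back into the source rows."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]

    def backward(g):
        acc = np.zeros_like(x.data)
        np.add.at(acc, idx, g)
        x._accumulate(acc)

    return Tensor(out_data, (x,), backward)


def segment_sum(x: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    """Row-wise scatter-add: out[s] = sum of x rows with idx == s.

    Rows of x index into `num_segments` output slots; the gradient of a slot
    is gathered back to every contributing row.
    """
    idx = np.asarray(idx, dtype=np.intp)
    out_data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, idx, x.data)

    def backward(g):
        x._accumulate(g[idx])

    return Tensor(out_data, (x,), backward)


def hstack(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[-1]
    out_data = np.concatenate([a.data, b.data], axis=-1)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g[..., :na])
        if b.requires_grad:
            b._accumulate(g[..., na:])

    return Tensor(out_data, (a, b), backward)


def sum_all(x: Tensor) -> Tensor:
    out_data = np.asarray(x.data.sum())

    def backward(g):
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return Tensor(out_data, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy from logits, numerically stable.

    Per element: softplus(z) - z*y.  `mask` (0/1) excludes elements (e.g.
    missing labels) from both the sum and the normalizing count.
    """
    targets = np.asarray(targets, dtype=np.float64)
    if mask is None:
        mask = np.ones_like(targets)
    mask = np.asarray(mask, dtype=np.float64)
    n = mask.sum()
    if n == 0:
        raise ValueError("bce_with_logits: mask excludes every element")
    per_elem = sub(softplus(logits), mul(logits, Tensor(targets)))
    return mul(sum_all(mul(per_elem, Tensor(mask))), Tensor(1.0 / n))


def mse(pred: Tensor, targets: np.ndarray) -> Tensor:
    """Mean squared error over all elements."""
    targets = np.asarray(targets, dtype=np.float64)
    diff = sub(pred, Tensor(targets))
    n = targets.size
    return mul(sum_all(mul(diff, diff)), Tensor(1.0 / n))
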