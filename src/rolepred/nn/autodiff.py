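"""Minimal vectorized reverse-mode automatic differentiation.

Array-valued tape autodiff sufficient for small LSTM models: matmul,
broadcasting add/mul, tanh/sigmoid, concatenation, row gathering, column
slicing and a fused softmax cross-entropy.  Everything is float64 numpy;
no external framework is required, which keeps the model runnable in a
CPU-only environment.
"""

from __future__ import annotations

import contextlib
from typing import Callable

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep numpy from hijacking operators

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED[-1]
        self._parents = parents if self.requires_grad or any(p.requires_grad for p in parents) else ()
        self._backward = backward

    # -- construction helpers ----------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
            out = Tensor(data, requires_grad=True)
            out._parents = parents
            out._backward = backward
            return out
        return Tensor(data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __sub__(self, other):
        return self + (self._wrap(other) * -1.0)

    def __rsub__(self, other):
        return self._wrap(other) + (self * -1.0)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    # -- nonlinearities -----------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 0.5 * (np.tanh(0.5 * self.data) + 1.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def slice_cols(self, start: int, stop: int):
        out_data = self.data[:, start:stop]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[:, start:stop] = g
                self._accum(full)

        return self._make(out_data, (self,), backward)

    def sum(self):
        out_data = self.data.sum()

        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self):
        n = self.data.size
        out_data = self.data.mean()

        def backward(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g / n, self.data.shape).copy())

        return self._make(out_data, (self,), backward)

    # -- autodiff driver ----------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    offsets = np.cumsum([0] + [d.shape[axis] for d in datas])

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    ref = tensors[0]
    return ref._make(out_data, tuple(tensors), backward)


def gather_rows(t: Tensor, idx) -> Tensor:
    idx = np.asarray(idx, dtype=np.intp)
    out_data = t.data[idx]

    def backward(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, idx, g)
            t._accum(full)

    return t._make(out_data, (t,), backward)


def softmax_cross_entropy(logits: Tensor, targets, weights=None) -> Tensor:
    """Mean (optionally weighted) cross-entropy of row-wise softmax vs integer targets.

    ``weights`` (length = rows) masks/weights rows; the loss is
    ``sum(w_i * ce_i) / sum(w_i)``.
    """
    targets = np.asarray(targets, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.data.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=np.float64)
    wsum = w.sum()
    logp = z[np.arange(n), targets] - np.log(ez.sum(axis=1))
    out_data = -(w * logp).sum() / wsum

    def backward(g):
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(n), targets] -= 1.0
            grad *= (w / wsum)[:, None]
            logits._accum(g * grad)

    return logits._make(np.asarray(out_data), (logits,), backward)


def softmax_np(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)
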