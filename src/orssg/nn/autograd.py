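"""A minimal reverse-mode autodiff engine on numpy arrays.

Supports exactly the operations the scene-graph network needs: affine maps,
ReLU, axis reductions (max / mean / sum), concatenation, row gathering,
im2col-based 2D convolution and a fused weighted softmax cross-entropy.
Gradients are accumulated by topological backward traversal.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "softmax_cross_entropy", "Adam"]


class Tensor:
    """A numpy array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- graph construction helpers -------------------------------------

    @staticmethod
    def _node(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- operations ------------------------------------------------------

    def __matmul__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accumulate(grad @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ grad)

        return Tensor._node(a.data @ b.data, (a, b), backward)

    def __add__(self, other: "Tensor") -> "Tensor":
        a, b = self, other

        def backward(grad):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad, b.data.shape))

        return Tensor._node(a.data + b.data, (a, b), backward)

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + other * (-1.0)

    def __mul__(self, scalar: float) -> "Tensor":
        a = self
        s = float(scalar)

        def backward(grad):
            if a.requires_grad:
                a._accumulate(grad * s)

        return Tensor._node(a.data * s, (a,), backward)

    __rmul__ = __mul__

    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def backward(grad):
            if a.requires_grad:
                a._accumulate(grad * mask)

        return Tensor._node(a.data * mask, (a,), backward)

    def reshape(self, *shape: int) -> "Tensor":
        a = self
        old = a.data.shape

        def backward(grad):
            if a.requires_grad:
                a._accumulate(grad.reshape(old))

        return Tensor._node(a.data.reshape(shape), (a,), backward)

    def max(self, axis: int) -> "Tensor":
        """Max over one axis; ties propagate to the first argmax (like numpy)."""
        a = self
        idx = np.argmax(a.data, axis=axis)
        out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)

        def backward(grad):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.put_along_axis(
                    full, np.expand_dims(idx, axis), np.expand_dims(grad, axis), axis=axis
                )
                a._accumulate(full)

        return Tensor._node(out, (a,), backward)

    def mean(self, axis: int) -> "Tensor":
        a = self
        n = a.data.shape[axis]

        def backward(grad):
            if a.requires_grad:
                a._accumulate(np.repeat(np.expand_dims(grad / n, axis), n, axis=axis))

        return Tensor._node(a.data.mean(axis=axis), (a,), backward)

    def sum(self) -> "Tensor":
        a = self

        def backward(grad):
            if a.requires_grad:
                a._accumulate(np.full_like(a.data, grad))

        return Tensor._node(a.data.sum(), (a,), backward)

    # -- backprop --------------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate graph state
                node._backward = None
                node._parents = ()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    parts = list(tensors)
    sizes = [t.data.shape[axis] for t in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(np.take(grad, range(lo, hi), axis=axis))

    return Tensor._node(np.concatenate([t.data for t in parts], axis=axis), parts, backward)


def gather_rows(tensor: Tensor, indices: np.ndarray) -> Tensor:
    """Select rows (first axis) by integer index; backward scatter-adds."""
    a = tensor
    idx = np.asarray(indices, dtype=np.int64)

    def backward(grad):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, grad)
            a._accumulate(full)

    return Tensor._node(a.data[idx], (a,), backward)


def softmax_cross_entropy(
    logits: Tensor,
    targets: np.ndarray,
    weights: np.ndarray | None = None,
) -> Tensor:
    """Mean (optionally per-class weighted) cross-entropy over rows.

    ``targets`` are integer class indices; rows with target -1 are ignored.
    """
    a = logits
    targets = np.asarray(targets, dtype=np.int64)
    keep = targets >= 0
    if not keep.any():
        return Tensor(0.0)
    z = a.data[keep]
    t = targets[keep]
    z = z - z.max(axis=1, keepdims=True)
    exp = np.exp(z)
    probs = exp / exp.sum(axis=1, keepdims=True)
    w = np.ones(len(t)) if weights is None else np.asarray(weights, dtype=np.float64)[t]
    losses = -np.log(np.clip(probs[np.arange(len(t)), t], 1e-12, None))
    denom = w.sum()
    loss_value = float((w * losses).sum() / denom)

    def backward(grad):
        if a.requires_grad:
            g = probs.copy()
            g[np.arange(len(t)), t] -= 1.0
            g *= (w / denom)[:, None] * grad
            full = np.zeros_like(a.data)
            full[keep] = g
            a._accumulate(full)

    return Tensor._node(np.float64(loss_value), (a,), backward)


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
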