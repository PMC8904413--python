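"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the attention
network needs: broadcast arithmetic, matmul, reductions, exp/log, the
LeakyReLU/ELU/ReLU nonlinearities, concatenation, reshape and row
gathering. Gradients are float64 throughout and are validated against
central finite differences in the test suite.

Only scalars (via ``backward()`` on a 0-d result) start a backward pass.
"""

from __future__ import annotations

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; tapes can exceed the recursion limit
            node, processed = stack.pop()
            if id(node) in seen:
                continue
            if processed:
                seen.add(id(node))
                topo.append(node)
                continue
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: Array) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return Tensor(self.data / other.data, parents=(self, other), backward=bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T if other.data.ndim > 1
                                 else np.outer(g, other.data))
            if other.requires_grad:
                other._accumulate(self.data.T @ g if self.data.ndim > 1
                                  else np.outer(self.data, g))

        return Tensor(self.data @ other.data, parents=(self, other), backward=bw)

    # -- shape ops ---------------------------------------------------------
    @property
    def T(self):
        def bw(g):
            self._accumulate(g.T)

        return Tensor(self.data.T, parents=(self,), backward=bw)

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=bw)

    def take_rows(self, idx) -> "Tensor":
        idx = np.asarray(idx, dtype=int)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor(self.data[idx], parents=(self,), backward=bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                grad = np.broadcast_to(g, self.shape).astype(float)
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(g2, self.shape)
            self._accumulate(np.ascontiguousarray(grad))

        return Tensor(out_data, parents=(self,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward=bw)

    def log(self):
        def bw(g):
            self._accumulate(g / self.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return Tensor(self.data * mask, parents=(self,), backward=bw)

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._accumulate(g * factor)

        return Tensor(self.data * factor, parents=(self,), backward=bw)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def bw(g):
            self._accumulate(g * np.where(pos, 1.0, out_data + alpha))

        return Tensor(out_data, parents=(self,), backward=bw)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=bw,
    )


def masked_softmax(scores: Tensor, mask: Array, axis: int = -1) -> Tensor:
    """Row softmax restricted to ``mask`` (0/1 array); masked entries are
    exactly zero in the output and carry no gradient."""
    neg = np.where(mask > 0, 0.0, -np.inf)
    shifted = scores + Tensor(neg)
    # subtract detached row max for numerical stability
    row_max = np.max(np.where(mask > 0, scores.data, -np.inf), axis=axis, keepdims=True)
    e = (shifted - Tensor(row_max)).exp() * Tensor(mask.astype(float))
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(logits: Tensor) -> Tensor:
    """Numerically stable log-softmax over the last axis of a vector."""
    shift = logits - Tensor(np.max(logits.data, axis=-1, keepdims=True))
    return shift - shift.exp().sum(axis=-1, keepdims=True).log()
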