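"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the graph network needs are provided: dense matmul,
broadcast arithmetic, row gather/scatter (the sparse message-passing
primitives), segment softmax building blocks, ELU/LeakyReLU, reductions
and absolute value.  Gradients are accumulated in float64; correctness is
pinned by a central-finite-difference check in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    value : array_like
        The forward value, stored as float64.
    parents : tuple
        ``(tensor, vjp)`` pairs; ``vjp`` maps the output cotangent to the
        parent's cotangent contribution.
    requires_grad : bool
        Leaves with ``requires_grad=True`` accumulate ``.grad``.
    """

    __slots__ = ("value", "parents", "requires_grad", "grad")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.parents = parents
        self.requires_grad = requires_grad
        self.grad = None

    # ----- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.value.shape

    def _topo(self):
        # iterative post-order DFS; graphs from long training loops are deep
        order, seen = [], set()
        stack: list[tuple["Tensor", bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        return order

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` (summed if non-scalar) into leaves."""
        if seed is None:
            seed = np.ones_like(self.value)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(seed, dtype=np.float64)}
        for node in reversed(self._topo()):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node.parents:
                contrib = vjp(g)
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + contrib
                else:
                    grads[id(parent)] = contrib

    # ----- arithmetic --------------------------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.value + other.value,
            parents=(
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ),
        )

    __radd__ = __add__

    def __sub__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.value - other.value,
            parents=(
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(-g, other.shape)),
            ),
        )

    def __rsub__(self, other):
        return self._coerce(other) - self

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.value * other.value,
            parents=(
                (self, lambda g: _unbroadcast(g * other.value, self.shape)),
                (other, lambda g: _unbroadcast(g * self.value, other.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.value / other.value,
            parents=(
                (self, lambda g: _unbroadcast(g / other.value, self.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.value / (other.value**2), other.shape
                    ),
                ),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __neg__(self):
        return Tensor(-self.value, parents=((self, lambda g: -g),))

    def __matmul__(self, other):
        other = self._coerce(other)
        return Tensor(
            self.value @ other.value,
            parents=(
                (self, lambda g: g @ other.value.T),
                (other, lambda g: self.value.T @ g),
            ),
        )

    # ----- nonlinearities ----------------------------------------------------

    def elu(self, alpha: float = 1.0) -> "Tensor":
        x = self.value
        out = np.where(x > 0, x, alpha * np.expm1(x))
        dx = np.where(x > 0, 1.0, alpha * np.exp(x))
        return Tensor(out, parents=((self, lambda g: g * dx),))

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        x = self.value
        dx = np.where(x > 0, 1.0, slope)
        return Tensor(x * dx, parents=((self, lambda g: g * dx),))

    def exp(self) -> "Tensor":
        out = np.exp(self.value)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def abs(self) -> "Tensor":
        s = np.sign(self.value)  # subgradient 0 at 0
        return Tensor(np.abs(self.value), parents=((self, lambda g: g * s),))

    def sqrt(self) -> "Tensor":
        out = np.sqrt(self.value)
        return Tensor(out, parents=((self, lambda g: g * 0.5 / out),))

    # ----- reductions & shaping ----------------------------------------------

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = self.value.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.shape).copy()

        return Tensor(out, parents=((self, vjp),))

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        return Tensor(
            self.value.reshape(*shape),
            parents=((self, lambda g: g.reshape(self.shape)),),
        )

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Rows ``self[index]``; the backward pass scatter-adds."""
        index = np.asarray(index, dtype=np.intp)

        def vjp(g):
            out = np.zeros_like(self.value)
            np.add.at(out, index, g)
            return out

        return Tensor(self.value[index], parents=((self, vjp),))

    def scatter_add_rows(self, index: np.ndarray, n_rows: int) -> "Tensor":
        """Segment sum: out[k] = sum over rows i with index[i] == k."""
        index = np.asarray(index, dtype=np.intp)
        out = np.zeros((n_rows,) + self.value.shape[1:], dtype=np.float64)
        np.add.at(out, index, self.value)
        return Tensor(out, parents=((self, lambda g: g[index]),))


def constant(value) -> Tensor:
    return Tensor(value)


def parameter(value) -> Tensor:
    return Tensor(np.array(value, dtype=np.float64), requires_grad=True)
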