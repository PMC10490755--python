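"""Compact reverse-mode automatic differentiation on numpy arrays.

The deformation and feature networks in this package are small graph/point
networks (a few dozen dense layers over at most a few tens of thousands of
rows), so a minimal tape-based engine over numpy matmuls is sufficient to
train them on a CPU.  Only the operations those networks need are provided:
dense matmul, ReLU, gather/segment-sum (for message passing on mesh graphs),
max-pooling over a group axis (for the per-region PointNet encoder), and the
elementwise arithmetic used by the Chamfer / normal / edge losses.

Gradients are accumulated by topological traversal of the recorded tape.
``Tensor`` wraps an ndarray; ``Parameter`` marks a leaf that optimizers
update.  ``Adam`` implements the standard first/second-moment update.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Adam",
    "concat",
    "segment_sum",
    "spmm",
    "cross",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "_parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p, _ in parents)
        # parents: sequence of (Tensor, fn) where fn maps upstream grad -> parent grad
        self._parents = tuple((p, fn) for p, fn in parents if p.requires_grad)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo, seen = [], set()
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
            for p, _ in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
            for p, fn in node._parents:
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data + other.data,
            parents=[
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, parents=[(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data * other.data,
            parents=[
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data / other.data,
            parents=[
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.data.shape
                    ),
                ),
            ],
        )

    def __matmul__(self, other):
        other = self._wrap(other)
        return Tensor(
            self.data @ other.data,
            parents=[
                (
                    self,
                    lambda g: _unbroadcast(
                        g @ np.swapaxes(other.data, -1, -2), self.data.shape
                    ),
                ),
                (
                    other,
                    lambda g: _unbroadcast(
                        np.swapaxes(self.data, -1, -2) @ g, other.data.shape
                    ),
                ),
            ],
        )

    # ------------------------------------------------------------ elementwise
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=[(self, lambda g: g * mask)])

    def abs(self):
        sign = np.sign(self.data)
        return Tensor(np.abs(self.data), parents=[(self, lambda g: g * sign)])

    def square(self):
        return self * self

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor(out, parents=[(self, lambda g: g * 0.5 / np.maximum(out, 1e-30))])

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(out, parents=[(self, back)])

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis: int):
        """Max over one axis; gradient flows to the (first) argmax entries."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        out = np.squeeze(out, axis=axis)

        def back(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(
                full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            return full

        return Tensor(out, parents=[(self, back)])

    # ------------------------------------------------------------- structural
    def gather(self, index):
        """Select rows: out[i...] = self[index[i...]] (index into axis 0)."""
        index = np.asarray(index)
        out = self.data[index]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, index, g)
            return full

        return Tensor(out, parents=[(self, back)])

    def __getitem__(self, key):
        out = self.data[key]

        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return full

        return Tensor(out, parents=[(self, back)])

    def reshape(self, *shape):
        return Tensor(
            self.data.reshape(*shape),
            parents=[(self, lambda g: g.reshape(self.data.shape))],
        )


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def concat(tensors, axis: int = -1) -> Tensor:
    """Concatenate tensors along an axis, with gradient splitting."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def make_back(i):
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        sl = tuple(sl)
        return lambda g: g[sl]

    return Tensor(out, parents=[(t, make_back(i)) for i, t in enumerate(tensors)])


def segment_sum(values: Tensor, segment_ids, num_segments: int) -> Tensor:
    """Sum rows of `values` into `num_segments` buckets (message aggregation)."""
    segment_ids = np.asarray(segment_ids)
    out = np.zeros((num_segments,) + values.data.shape[1:], dtype=values.data.dtype)
    np.add.at(out, segment_ids, values.data)
    return Tensor(out, parents=[(values, lambda g: g[segment_ids])])


def spmm(matrix, x: Tensor, matrix_t=None) -> Tensor:
    """Multiply a constant scipy sparse matrix with a dense Tensor.

    Used for neighbour aggregation on mesh graphs, where the adjacency is
    fixed; `matrix_t` defaults to `matrix` (correct for symmetric adjacency).
    """
    mt = matrix if matrix_t is None else matrix_t
    return Tensor(matrix @ x.data, parents=[(x, lambda g: mt @ g)])


def cross(a: Tensor, b: Tensor) -> Tensor:
    """Row-wise 3D cross product a x b."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    out = np.cross(a.data, b.data)
    return Tensor(
        out,
        parents=[
            (a, lambda g: np.cross(b.data, g)),
            (b, lambda g: np.cross(g, a.data)),
        ],
    )


class Adam:
    """Adam optimizer with optional externally-driven learning-rate changes."""

    def __init__(self, params, lr: float = 5.0e-5, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
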