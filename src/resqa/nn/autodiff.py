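"""Minimal reverse-mode automatic differentiation on numpy arrays.

A ``Tensor`` wraps an ndarray and remembers how it was produced; calling
``backward()`` on a scalar loss accumulates gradients into every upstream
tensor created with ``requires_grad=True``.  The op set is exactly what the
predictors need: broadcast arithmetic, matmul, 1-D convolution (same
padding), gather / segment-mean for graph message passing, the activation
functions, concatenation and reductions.  Everything is float64 and
single-threaded, which keeps training bitwise reproducible for a fixed
seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather", "segment_mean", "conv1d_same",
           "mse_loss"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph traversal ----------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)
        out = Tensor(self.data - other.data, parents=(self, other))
        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(-g, other.shape))
        out._backward = bw
        return out

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)
        out._backward = bw
        return out

    def __neg__(self):
        return self * (-1.0)

    # -- activations --------------------------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        mask = self.data > 0
        out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.01):
        y = np.where(self.data > 0, self.data, slope * self.data)
        out = Tensor(y, parents=(self,))
        factor = np.where(self.data > 0, 1.0, slope)
        out._backward = lambda g: self._accum(g * factor)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    # -- reductions & shaping -----------------------------------------------

    def sum(self):
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g, self.shape).copy())
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        out._backward = lambda g: self._accum(
            np.broadcast_to(g / n, self.shape).copy())
        return out

    def mean_axis0(self, keepdims: bool = True):
        n = self.data.shape[0]
        out = Tensor(self.data.mean(axis=0, keepdims=keepdims),
                     parents=(self,))
        def bw(g):
            gg = g if keepdims else g[None, :]
            self._accum(np.broadcast_to(gg / n, self.shape).copy())
        out._backward = bw
        return out

    def reshape(self, *shape):
        old = self.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(old))
        return out

    def pow(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda g: self._accum(
            g * exponent * self.data ** (exponent - 1.0))
        return out

    def sqrt(self):
        return self.pow(0.5)


# ---------------------------------------------------------------------------
# free-function ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])
    out._backward = bw
    return out


def gather(x: Tensor, idx: np.ndarray) -> Tensor:
    """Row gather: out[i] = x[idx[i]]."""
    idx = np.asarray(idx, dtype=int)
    out = Tensor(x.data[idx], parents=(x,))
    def bw(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, idx, g)
        x._accum(gx)
    out._backward = bw
    return out


def segment_mean(x: Tensor, segment_ids: np.ndarray,
                 num_segments: int) -> Tensor:
    """Mean of the rows of ``x`` grouped by ``segment_ids``.

    Segments with no members yield zero rows (and receive no gradient).
    """
    seg = np.asarray(segment_ids, dtype=int)
    counts = np.bincount(seg, minlength=num_segments).astype(float)
    safe = np.maximum(counts, 1.0)
    sums = np.zeros((num_segments, x.data.shape[1]))
    np.add.at(sums, seg, x.data)
    out = Tensor(sums / safe[:, None], parents=(x,))
    def bw(g):
        x._accum(g[seg] / safe[seg, None])
    out._backward = bw
    return out


def conv1d_same(x: Tensor, weight: Tensor, bias: Tensor,
                kernel: int) -> Tensor:
    """1-D convolution over the length axis with same padding.

    ``x`` is (L, C_in); ``weight`` is (C_in * kernel, C_out) — the kernel
    taps of each input channel stacked position-major; ``bias`` is (C_out,).
    Implemented as im2col + matmul so the backward pass is a col2im
    scatter.
    """
    L, cin = x.data.shape
    pad = kernel // 2
    xp = np.zeros((L + 2 * pad, cin))
    xp[pad:pad + L] = x.data
    # cols[i] = xp[i : i+kernel] flattened position-major
    cols = np.empty((L, kernel * cin))
    for t in range(kernel):
        cols[:, t * cin:(t + 1) * cin] = xp[t:t + L]
    y = cols @ weight.data + bias.data
    out = Tensor(y, parents=(x, weight, bias))
    def bw(g):
        bias._accum(g.sum(axis=0))
        weight._accum(cols.T @ g)
        dcols = g @ weight.data.T
        dxp = np.zeros_like(xp)
        for t in range(kernel):
            dxp[t:t + L] += dcols[:, t * cin:(t + 1) * cin]
        x._accum(dxp[pad:pad + L])
    out._backward = bw
    return out


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=float))
    return (diff * diff).mean()
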