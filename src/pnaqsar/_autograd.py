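"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operations the PNA + fingerprint network needs:
dense algebra (matmul, broadcast add, elementwise ops, ReLU, concat) and the
segment operations that make message passing over batched molecular graphs
vectorizable (gather rows, segment sum/mean/max/min over edge destinations
and over graph membership).  Gradients flow through a topologically sorted
tape; max/min use the tie-sharing subgradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    __slots__ = ("data", "grad", "_backward", "_parents", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph walk ---------------------------------------------------------

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

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __sub__(self, other):
        return self + (self._lift(other) * -1.0)

    def __rsub__(self, other):
        return self._lift(other) + (self * -1.0)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bwd
        return out

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bwd
        return out

    def sqrt(self, eps: float = 0.0) -> "Tensor":
        val = np.sqrt(self.data + eps)
        out = Tensor(val, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(val, 1e-30))

        out._backward = bwd
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, float(g)))

        out._backward = bwd
        return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a gradient back to the shape it was broadcast from."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the feature (last) axis."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=-1), tuple(tensors))
    widths = [t.data.shape[-1] for t in tensors]

    def bwd(g):
        pos = 0
        for t, w in zip(tensors, widths):
            if t.requires_grad:
                t._accum(g[..., pos:pos + w])
            pos += w

    out._backward = bwd
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    out = Tensor(x.data[idx], (x,))

    def bwd(g):
        if x.requires_grad:
            acc = np.zeros_like(x.data)
            np.add.at(acc, idx, g)
            x._accum(acc)

    out._backward = bwd
    return out


def segment_sum(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    val = np.zeros((n_seg, x.data.shape[1]))
    np.add.at(val, seg, x.data)
    out = Tensor(val, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g[seg])

    out._backward = bwd
    return out


def segment_mean(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    counts = np.bincount(seg, minlength=n_seg).astype(np.float64)
    safe = np.maximum(counts, 1.0)[:, None]
    s = segment_sum(x, seg, n_seg)
    return s * Tensor(1.0 / safe)


def _segment_extreme(x: Tensor, seg: np.ndarray, n_seg: int, mode: str) -> Tensor:
    fill = -np.inf if mode == "max" else np.inf
    val = np.full((n_seg, x.data.shape[1]), fill)
    ufunc = np.maximum if mode == "max" else np.minimum
    ufunc.at(val, seg, x.data)
    empty = ~np.isfinite(val)
    val = np.where(empty, 0.0, val)  # empty segments contribute zeros
    out = Tensor(val, (x,))

    def bwd(g):
        if not x.requires_grad:
            return
        hit = (x.data == val[seg]) & ~empty[seg]
        # split gradient equally among ties (deterministic subgradient)
        n_hits = np.zeros((n_seg, x.data.shape[1]))
        np.add.at(n_hits, seg, hit.astype(np.float64))
        share = np.where(hit, 1.0 / np.maximum(n_hits[seg], 1.0), 0.0)
        x._accum(g[seg] * share)

    out._backward = bwd
    return out


def segment_max(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    return _segment_extreme(x, seg, n_seg, "max")


def segment_min(x: Tensor, seg: np.ndarray, n_seg: int) -> Tensor:
    return _segment_extreme(x, seg, n_seg, "min")


def segment_std(x: Tensor, seg: np.ndarray, n_seg: int, eps: float = 1e-8) -> Tensor:
    """Population standard deviation per segment: sqrt(E[x^2] - E[x]^2 + eps).

    Zero for empty and single-element segments (up to sqrt(eps)).
    """
    m = segment_mean(x, seg, n_seg)
    m2 = segment_mean(x * x, seg, n_seg)
    var = m2 - m * m
    pos = var.data > 0  # exact 0 for empty/single-element segments
    val = np.where(pos, np.sqrt(np.maximum(var.data, 0.0) + eps), 0.0)
    out = Tensor(val, (var,))

    def bwd(g):
        if var.requires_grad:
            var._accum(np.where(pos, g * 0.5 / np.maximum(val, 1e-30), 0.0))

    out._backward = bwd
    return out
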