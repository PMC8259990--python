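"""Minimal reverse-mode automatic differentiation over numpy arrays.

The transformer in :mod:`condlm.model` needs gradients for a dozen array
operations (matmul, broadcast add/mul, ReLU, log-softmax, layer
normalization, embedding lookup and a few shape manipulations).  This module
provides exactly those as a small tape-based autodiff engine: every
:class:`Tensor` records the operation that produced it and a closure that
propagates the upstream gradient to its parents; :meth:`Tensor.backward`
walks the graph in reverse topological order.

Arrays are kept in float64 throughout, which keeps finite-difference
gradient checks tight at the model scales this package targets.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "matmul",
    "exp",
    "relu",
    "log_softmax",
    "layer_norm",
    "embedding",
    "take_last_axis",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
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
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_pending")
    __array_priority__ = 100  # make ndarray + Tensor dispatch to us

    def __init__(self, data, requires_grad: bool = False) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------------
    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` w.r.t. every upstream tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

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

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            # leaves accumulate into .grad; interior nodes dispatch to parents
            node._dispatch(g, grads)

    def _dispatch(self, g: np.ndarray, grads: dict[int, np.ndarray]) -> None:
        # _backward closures push parent gradients via this helper
        self._pending = grads  # type: ignore[attr-defined]
        try:
            self._backward(g)  # type: ignore[misc]
        finally:
            del self._pending

    def _send(self, parent: "Tensor", g: np.ndarray) -> None:
        if not parent.requires_grad:
            return
        grads = self._pending  # type: ignore[attr-defined]
        if parent._backward is None:
            parent.grad = g if parent.grad is None else parent.grad + g
        else:
            key = id(parent)
            grads[key] = g if key not in grads else grads[key] + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(g: np.ndarray, out=None) -> None:
            out._send(self, _unbroadcast(g, self.shape))
            out._send(other, _unbroadcast(g, other.shape))

        out = self._make(out_data, (self, other), lambda g: backward(g, out))
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g: np.ndarray, out=None) -> None:
            out._send(self, -g)

        out = self._make(-self.data, (self,), lambda g: backward(g, out))
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(g: np.ndarray, out=None) -> None:
            out._send(self, _unbroadcast(g * other.data, self.shape))
            out._send(other, _unbroadcast(g * self.data, other.shape))

        out = self._make(out_data, (self, other), lambda g: backward(g, out))
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape

        def backward(g: np.ndarray, out=None) -> None:
            out._send(self, g.reshape(old))

        out = self._make(self.data.reshape(*shape), (self,), lambda g: backward(g, out))
        return out

    def transpose(self, *axes: int) -> "Tensor":
        inverse = tuple(int(np.argsort(axes)[i]) for i in range(len(axes)))

        def backward(g: np.ndarray, out=None) -> None:
            out._send(self, g.transpose(inverse))

        out = self._make(self.data.transpose(axes), (self,), lambda g: backward(g, out))
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.shape

        def backward(g: np.ndarray, out=None) -> None:
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            out._send(self, np.broadcast_to(gg, shape).copy())

        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,),
                         lambda g: backward(g, out))
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product; leading axes broadcast as in ``np.matmul``."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)

    def backward(g: np.ndarray, out=None) -> None:
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        out._send(a, _unbroadcast(ga, a.shape))
        out._send(b, _unbroadcast(gb, b.shape))

    out = a._make(out_data, (a, b), lambda g: backward(g, out))
    return out


def exp(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out_data = np.exp(x.data)

    def backward(g: np.ndarray, out=None) -> None:
        out._send(x, g * out_data)

    out = x._make(out_data, (x,), lambda g: backward(g, out))
    return out


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0

    def backward(g: np.ndarray, out=None) -> None:
        out._send(x, g * mask)

    out = x._make(np.where(mask, x.data, 0.0), (x,), lambda g: backward(g, out))
    return out


def log_softmax(x: Tensor, additive_mask: np.ndarray | None = None) -> Tensor:
    """Log-softmax over the last axis.

    ``additive_mask`` (a constant, not differentiated) is added to the logits
    first; use large negative values to exclude positions.
    """
    x = _as_tensor(x)
    z = x.data if additive_mask is None else x.data + additive_mask
    zmax = z.max(axis=-1, keepdims=True)
    shifted = z - zmax
    lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    out_data = shifted - lse
    softmax = np.exp(out_data)

    def backward(g: np.ndarray, out=None) -> None:
        out._send(x, g - softmax * g.sum(axis=-1, keepdims=True))

    out = x._make(out_data, (x,), lambda g: backward(g, out))
    return out


def layer_norm(x: Tensor, gain: Tensor, offset: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize the last axis to zero mean / unit variance, then affine."""
    x = _as_tensor(x)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + offset.data
    n = x.data.shape[-1]

    def backward(g: np.ndarray, out=None) -> None:
        out._send(gain, _unbroadcast(g * xhat, gain.shape))
        out._send(offset, _unbroadcast(g, offset.shape))
        gy = g * gain.data
        # d xhat / d x for per-row normalization
        gx = inv * (gy - gy.mean(axis=-1, keepdims=True)
                    - xhat * (gy * xhat).mean(axis=-1, keepdims=True))
        out._send(x, gx)

    out = x._make(out_data, (x, gain, offset), lambda g: backward(g, out))
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids, dtype=np.int64)
    out_data = table.data[ids]

    def backward(g: np.ndarray, out=None) -> None:
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        out._send(table, gt)

    out = table._make(out_data, (table,), lambda g: backward(g, out))
    return out


def take_last_axis(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``x[..., idx[...]]`` along the last axis (for cross-entropy)."""
    x = _as_tensor(x)
    idx = np.asarray(idx, dtype=np.int64)
    out_data = np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0]

    def backward(g: np.ndarray, out=None) -> None:
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        out._send(x, gx)

    out = x._make(out_data, (x,), lambda g: backward(g, out))
    return out


def parameters(tree) -> Iterable[Tensor]:
    """Yield every Tensor in a (possibly nested) dict of parameters."""
    if isinstance(tree, Tensor):
        yield tree
    elif isinstance(tree, dict):
        for v in tree.values():
            yield from parameters(v)
    elif isinstance(tree, (list, tuple)):
        for v in tree:
            yield from parameters(v)
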