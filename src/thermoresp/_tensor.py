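"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Supports exactly the operations the two-pathway video regressor needs:
broadcasting arithmetic, matmul, ReLU, reductions (sum / mean / max),
reshape, concatenation, square root and strided, padded 3-D convolution
(implemented as im2col + matmul, with a scatter-add col2im backward pass).
Gradient correctness is established by finite-difference tests.

Design notes
------------
* A :class:`Tensor` wraps an ``ndarray`` and, when it results from an
  operation, holds a closure that routes the output gradient to its parent
  tensors.  ``backward()`` runs a topological sort of the tape.
* Broadcasting is handled by summing output gradients over broadcast axes
  (``_unbroadcast``).
* Everything is dtype-agnostic; the network uses float32, the gradient
  checks float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: np.ndarray) -> None:
        # First contribution borrows the array (ops hand over fresh
        # temporaries); later contributions add out of place, so the
        # borrowed buffer is never mutated.
        if grad.dtype != self.data.dtype:
            grad = grad.astype(self.data.dtype)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [t]
            order = []
            while stack:
                node = stack.pop()
                if id(node) in seen:
                    continue
                seen.add(id(node))
                order.append(node)
                stack.extend(node._prev)
            # order is a DFS pre-order; sort children before parents below
            topo.extend(order)

        visit(self)
        # Kahn-style ordering: repeatedly emit nodes whose consumers are done.
        indeg: dict[int, int] = {id(t): 0 for t in topo}
        for t in topo:
            for p in t._prev:
                indeg[id(p)] += 1
        ready = [t for t in topo if indeg[id(t)] == 0]
        ordered: list[Tensor] = []
        while ready:
            t = ready.pop()
            ordered.append(t)
            for p in t._prev:
                indeg[id(p)] -= 1
                if indeg[id(p)] == 0:
                    ready.append(p)

        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for t in ordered:
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None

    @staticmethod
    def _lift(other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            # float32 scalar so that float32 networks are not upcast;
            # float64 operands still promote normally.
            return Tensor(np.float32(other))
        return Tensor(np.asarray(other))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req, _prev=[p for p in parents if p.requires_grad])
        if req:
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return self._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def backward(g):
            a._accumulate(g * p * a.data ** (p - 1.0))

        return self._make(a.data**p, (a,), backward)

    def sqrt(self):
        return self**0.5

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    # -- nonlinearity and reductions ---------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return self._make(a.data * mask, (a,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                grad = np.broadcast_to(g, a.shape)
            else:
                gk = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(gk, a.shape)
            a._accumulate(np.ascontiguousarray(grad))

        return self._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        """Maximum reduction; gradient flows to the (first) argmax entries."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            expanded = out_data if keepdims or axis is None else np.expand_dims(out_data, axis)
            mask = a.data == expanded
            # split gradient evenly among ties
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            gk = g if keepdims or axis is None else np.expand_dims(g, axis)
            a._accumulate(mask * gk / counts)

        return self._make(out_data, (a,), backward)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = a.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return self._make(a.data.reshape(shape), (a,), backward)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            a._accumulate(g.transpose(inv))

        return self._make(a.data.transpose(axes), (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``."""
    datas = [t.data for t in tensors]
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]
    out_data = np.concatenate(datas, axis=axis)

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, part in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(part)

    return Tensor._make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# Fused batch normalisation
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Normalise over (N, T, H, W) per channel; returns (out, mean, var).

    Single fused primitive with the closed-form backward pass; ``mean`` and
    ``var`` are plain arrays for running-statistics bookkeeping.
    """
    axes = (0, 2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data
    m = x.data.size // x.data.shape[1]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes, keepdims=True))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes, keepdims=True))
        if x.requires_grad:
            gx = g * gamma.data
            t1 = gx.sum(axis=axes, keepdims=True)
            t2 = (gx * xhat).sum(axis=axes, keepdims=True)
            x._accumulate(inv * (gx - (t1 + xhat * t2) / m))

    return Tensor._make(out_data, (x, gamma, beta), backward), mu, var


# ---------------------------------------------------------------------------
# 3-D convolution (shift-and-matmul)
# ---------------------------------------------------------------------------

def conv3d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: tuple[int, int, int] = (1, 1, 1),
    pad: tuple[int, int, int] = (0, 0, 0),
) -> Tensor:
    """3-D convolution (cross-correlation) over (N, C, T, H, W) input.

    ``weight`` has shape ``(C_out, C_in, kt, kh, kw)``; output is
    ``(N, C_out, To, Ho, Wo)``.  Implemented as a sum of shifted, strided
    slices each contracted with one kernel tap by a matmul — faster than
    im2col for the small channel counts and kernels used here, and exactly
    equivalent.
    """
    n = x.shape[0]
    c_out, c_in, kt, kh, kw = weight.shape
    if x.shape[1] != c_in:
        raise ValueError(f"conv3d: input has {x.shape[1]} channels, weight expects {c_in}")
    st, sh, sw = stride
    pt, ph, pw = pad
    xp = x.data
    if pt or ph or pw:
        xp = np.pad(xp, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)))
    tp, hp, wp = xp.shape[2:]
    to = (tp - kt) // st + 1
    ho = (hp - kh) // sh + 1
    wo = (wp - kw) // sw + 1
    if to < 1 or ho < 1 or wo < 1:
        raise ValueError(
            f"conv3d: input {x.shape} too small for kernel {(kt, kh, kw)} "
            f"with stride {stride} and pad {pad}"
        )
    npos = to * ho * wo
    dtype = np.result_type(x.data, weight.data)
    wtaps = weight.data.reshape(c_out, c_in, -1)

    def tap_view(arr, i, j, k):
        return arr[:, :, i : i + st * to : st, j : j + sh * ho : sh, k : k + sw * wo : sw]

    acc = np.zeros((n, c_out, npos), dtype=dtype)
    for idx in range(kt * kh * kw):
        i, rem = divmod(idx, kh * kw)
        j, k = divmod(rem, kw)
        xm = tap_view(xp, i, j, k).reshape(n, c_in, npos)
        acc += np.matmul(wtaps[:, :, idx][None], xm)
    y = acc.reshape(n, c_out, to, ho, wo)
    if bias is not None:
        y = y + bias.data.reshape(1, -1, 1, 1, 1)

    parents = [p for p in (x, weight, bias) if p is not None]

    def backward(g):
        gm = g.reshape(n, c_out, npos)
        if bias is not None and bias.requires_grad:
            bias._accumulate(gm.sum(axis=(0, 2)))
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(weight.data) if weight.requires_grad else None
        for idx in range(kt * kh * kw):
            i, rem = divmod(idx, kh * kw)
            j, k = divmod(rem, kw)
            if weight.requires_grad:
                xm = tap_view(xp, i, j, k).reshape(n, c_in, npos)
                dw[:, :, i, j, k] = np.matmul(gm, xm.transpose(0, 2, 1)).sum(axis=0)
            if need_dx:
                dxs = np.matmul(wtaps[:, :, idx].T[None], gm)
                tap_view(dxp, i, j, k)[...] += dxs.reshape(n, c_in, to, ho, wo)
        if weight.requires_grad:
            weight._accumulate(dw)
        if need_dx:
            if pt or ph or pw:
                x._accumulate(dxp[:, :, pt : pt + x.shape[2], ph : ph + x.shape[3], pw : pw + x.shape[4]])
            else:
                x._accumulate(dxp)

    return Tensor._make(y, tuple(parents), backward)
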