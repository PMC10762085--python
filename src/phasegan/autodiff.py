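"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine powering the generator/critic networks in this
package.  Two properties matter here and drove the design:

* every vector-Jacobian product is itself expressed in terms of :class:`Tensor`
  operations, so gradients are differentiable — ``grad(..., create_graph=True)``
  enables the double backward needed by the WGAN gradient penalty (the penalty
  is a function of the critic's input-gradient, and training differentiates it
  again with respect to the critic's parameters);
* the primitive set is exactly what dense-block U-Nets need: broadcasted
  arithmetic, (batched) matmul, reshape/transpose/concat/slice, ``unfold``/
  ``fold`` for convolution via im2col, and nearest-neighbour up/down-sampling
  as an adjoint pair.

All arrays are float64.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "concat",
    "unfold",
    "fold",
    "upsample_nearest",
    "downsample_sum",
    "leaky_relu",
    "relu",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for reverse-mode autodiff."""

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._vjp = _vjp

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            # python scalars do not promote the array dtype
            return Tensor(
                self.data + other, _parents=(self,), _vjp=lambda g: (g,)
            )
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g, self.shape),
                _unbroadcast(g, other.shape),
            ),
        )
        return out

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=(self,), _vjp=lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return Tensor(
                self.data * other,
                _parents=(self,),
                _vjp=lambda g: (g * other,),
            )
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g * other, self.shape),
                _unbroadcast(g * self, other.shape),
            ),
        )
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        s = float(exponent)
        out = Tensor(
            self.data**s,
            _parents=(self,),
            _vjp=lambda g: (g * (s * self ** (s - 1.0)),),
        )
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,), _vjp=None)
        out._vjp = lambda g: (g * out,)
        return out

    def log(self):
        return Tensor(
            np.log(self.data), _parents=(self,), _vjp=lambda g: (g / self,)
        )

    def sqrt(self):
        return self**0.5

    def abs(self):
        sign = Tensor(np.sign(self.data))
        return Tensor(
            np.abs(self.data), _parents=(self,), _vjp=lambda g: (g * sign,)
        )

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.shape

        def vjp(g):
            if axis is None:
                return (broadcast_to(g.reshape((1,) * len(in_shape)), in_shape),)
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a % len(in_shape) for a in axes)
            if keepdims:
                gk = g
            else:
                kept = [1 if a in axes else in_shape[a] for a in range(len(in_shape))]
                gk = g.reshape(tuple(kept))
            return (broadcast_to(gk, in_shape),)

        return Tensor(out_data, _parents=(self,), _vjp=vjp)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else _axis_size(self.shape, axis)
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, shape):
        in_shape = self.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=(self,),
            _vjp=lambda g: (g.reshape(in_shape),),
        )

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        return Tensor(
            self.data.transpose(axes),
            _parents=(self,),
            _vjp=lambda g: (g.transpose(inv),),
        )

    def __getitem__(self, idx):
        in_shape = self.shape
        return Tensor(
            self.data[idx],
            _parents=(self,),
            _vjp=lambda g: (_scatter(g, idx, in_shape),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            np.matmul(self.data, other.data),
            _parents=(self, other),
            _vjp=lambda g: (
                _unbroadcast(g @ _swap_last(other), self.shape, batched_matmul=True),
                _unbroadcast(_swap_last(self) @ g, other.shape, batched_matmul=True),
            ),
        )
        return out


def as_tensor(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def _axis_size(shape, axis) -> int:
    axes = axis if isinstance(axis, tuple) else (axis,)
    n = 1
    for a in axes:
        n *= shape[a % len(shape)]
    return n


def _swap_last(t: Tensor) -> Tensor:
    if t.ndim < 2:
        raise ValueError("matmul operands must be at least 2-D")
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return t.transpose(axes)


def broadcast_to(t: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    in_shape = t.shape
    return Tensor(
        np.broadcast_to(t.data, shape),
        _parents=(t,),
        _vjp=lambda g: (_unbroadcast(g, in_shape),),
    )


def _unbroadcast(g: Tensor, target_shape, batched_matmul: bool = False) -> Tensor:
    """Sum ``g`` down to ``target_shape`` (inverse of numpy broadcasting)."""
    target_shape = tuple(target_shape)
    if g.shape == target_shape:
        return g
    extra = g.ndim - len(target_shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    keep = len(target_shape) - (2 if batched_matmul else 0)
    axes = tuple(
        i for i in range(keep) if target_shape[i] == 1 and g.shape[i] != 1
    )
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(target_shape)


def _scatter(g: Tensor, idx, shape) -> Tensor:
    """Adjoint of ``__getitem__``: place ``g`` into zeros of ``shape``."""
    out_data = np.zeros(shape, dtype=g.data.dtype)
    np.add.at(out_data, idx, g.data)

    def vjp(gg):
        return (gg[idx],)

    return Tensor(out_data, _parents=(g,), _vjp=vjp)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        grads = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            grads.append(g[tuple(sl)])
        return tuple(grads)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _vjp=vjp,
    )


# -- activations ---------------------------------------------------------------


def leaky_relu(t: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(t.data > 0, 1.0, slope).astype(t.data.dtype)
    mask_t = Tensor(mask)
    return Tensor(
        t.data * mask, _parents=(t,), _vjp=lambda g: (g * mask_t,)
    )


def relu(t: Tensor) -> Tensor:
    return leaky_relu(t, slope=0.0)


# -- im2col convolution support ------------------------------------------------


def _unfold_data(x: np.ndarray, ksize: int, stride: int, padding: int) -> np.ndarray:
    b, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (ksize, ksize), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]
    b, c, ho, wo, kh, kw = windows.shape
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols)


def _fold_data(
    cols: np.ndarray, out_hw, ksize: int, stride: int, padding: int
) -> np.ndarray:
    """Adjoint of :func:`_unfold_data` (scatter-add of column entries)."""
    h, w = out_hw
    b = cols.shape[0]
    c = cols.shape[1] // (ksize * ksize)
    hp, wp = h + 2 * padding, w + 2 * padding
    ho = (hp - ksize) // stride + 1
    wo = (wp - ksize) // stride + 1
    cols = cols.reshape(b, c, ksize, ksize, ho, wo)
    out = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    for i in range(ksize):
        for j in range(ksize):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                cols[:, :, i, j]
            )
    if padding:
        out = out[:, :, padding : padding + h, padding : padding + w]
    return out


def out_hw(h: int, w: int, ksize: int, stride: int, padding: int):
    return (
        (h + 2 * padding - ksize) // stride + 1,
        (w + 2 * padding - ksize) // stride + 1,
    )


def unfold(x: Tensor, ksize: int, stride: int = 1, padding: int = 0) -> Tensor:
    """im2col: [B,C,H,W] -> [B, C*k*k, H_out*W_out]."""
    hw = x.shape[2:]
    return Tensor(
        _unfold_data(x.data, ksize, stride, padding),
        _parents=(x,),
        _vjp=lambda g: (fold(g, hw, ksize, stride, padding),),
    )


def fold(cols: Tensor, hw, ksize: int, stride: int = 1, padding: int = 0) -> Tensor:
    """col2im scatter-add: adjoint of :func:`unfold`."""
    return Tensor(
        _fold_data(cols.data, hw, ksize, stride, padding),
        _parents=(cols,),
        _vjp=lambda g: (unfold(g, ksize, stride, padding),),
    )


def upsample_nearest(x: Tensor, p: int) -> Tensor:
    """Nearest-neighbour spatial upsampling by an integer factor."""
    return Tensor(
        x.data.repeat(p, axis=2).repeat(p, axis=3),
        _parents=(x,),
        _vjp=lambda g: (downsample_sum(g, p),),
    )


def downsample_sum(x: Tensor, p: int) -> Tensor:
    """Sum over non-overlapping p x p patches (adjoint of nearest upsampling)."""
    b, c, h, w = x.shape
    data = x.data.reshape(b, c, h // p, p, w // p, p).sum(axis=(3, 5))
    return Tensor(data, _parents=(x,), _vjp=lambda g: (upsample_nearest(g, p),))


# -- backward ------------------------------------------------------------------


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))
    return order


def grad(
    output: Tensor,
    inputs: Iterable[Tensor],
    create_graph: bool = False,
) -> list[Tensor]:
    """Gradients of a scalar ``output`` with respect to ``inputs``.

    With ``create_graph=True`` the returned gradients carry their own
    computation graph, so expressions built from them (e.g. a gradient-norm
    penalty) can be differentiated again.
    """
    inputs = list(inputs)
    if output.size != 1:
        raise ValueError("grad expects a scalar output")
    if not output.requires_grad:
        raise ValueError("output does not depend on any differentiable input")

    grads: dict[int, Tensor] = {
        id(output): Tensor(np.ones_like(output.data))
    }
    keep: dict[int, Tensor] = {id(output): output}  # guard against id reuse

    for node in reversed(_toposort(output)):
        g = grads.get(id(node))
        if g is None or node._vjp is None:
            continue
        parent_grads = node._vjp(g)
        for parent, pg in zip(node._parents, parent_grads):
            if not parent.requires_grad or pg is None:
                continue
            pid = id(parent)
            if pid in grads:
                grads[pid] = grads[pid] + pg
            else:
                grads[pid] = pg
                keep[pid] = parent

    out: list[Tensor] = []
    for x in inputs:
        g = grads.get(id(x))
        if g is None:
            g = Tensor(np.zeros_like(x.data))
        elif not create_graph:
            g = g.detach()
        out.append(g)
    return out
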