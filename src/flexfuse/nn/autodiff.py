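"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical engine behind every trainable component of the
package: the tabular encoding banks, the convolutional image branch, the
fusion operators, the Meta imputation network and the classifier head all
build computation graphs out of the ops defined here, and Integrated
Gradients differentiates the same graphs with respect to model *inputs*.

Design constraints:

* float64 throughout — determinism and gradient-check friendliness matter
  more than speed at the cohort sizes this package targets;
* every op registers a closure that accumulates into ``parent.grad``;
* broadcasting is supported on elementwise ops, with gradients reduced
  back to the parent shape by :func:`_unbroadcast`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "feature_affine", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # collapse axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(_parents)
        self._backward = _backward

    # ------------------------------------------------------------------ util
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # --------------------------------------------------------------- backward
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)
        # topological order over the subgraph that requires grad
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
        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ------------------------------------------------------------- elementwise
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        exponent = float(exponent)
        out = Tensor(
            self.data ** exponent,
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = _bw
        return out

    def _accum(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    # ------------------------------------------------------------- nonlinear
    def exp(self) -> "Tensor":
        val = np.exp(self.data)
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * val)

        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _bw
        return out

    def relu(self) -> "Tensor":
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        # numerically stable in both tails
        val = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, 0, None))),
            np.exp(np.clip(self.data, None, 0)) / (1.0 + np.exp(np.clip(self.data, None, 0))),
        )
        out = Tensor(val, requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g * val * (1.0 - val))

        out._backward = _bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            _parents=(self,),
        )

        def _bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            gg = g
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.data.ndim for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            self._accum(np.broadcast_to(gg, self.shape).copy() if np.ndim(gg) else np.full(self.shape, gg))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), requires_grad=self.requires_grad, _parents=(self,))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = _bw
        return out

    def transpose(self, axes: tuple[int, ...]) -> "Tensor":
        out = Tensor(self.data.transpose(axes), requires_grad=self.requires_grad, _parents=(self,))
        inv = tuple(np.argsort(axes))

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = _bw
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            _parents=(self, other),
        )

        def _bw(g: np.ndarray) -> None:
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        out._backward = _bw
        return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        _parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out._backward = _bw
    return out


# --------------------------------------------------------------------- conv2d
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    b, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]
    return cols.reshape(b, c * kh * kw, oh * ow), oh, ow


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, oh: int, ow: int) -> np.ndarray:
    b, c, h, w = xshape
    dx = np.zeros(xshape, dtype=dcols.dtype)
    d = dcols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[:, :, i, j]
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """Valid (no-padding) 2-D convolution, NCHW layout, square stride."""
    kh, kw = w.data.shape[2], w.data.shape[3]
    cols, oh, ow = _im2col(x.data, kh, kw, stride)
    w2 = w.data.reshape(w.data.shape[0], -1)
    out_val = np.matmul(w2, cols) + b.data[None, :, None]
    out = Tensor(
        out_val.reshape(x.data.shape[0], w.data.shape[0], oh, ow),
        requires_grad=x.requires_grad or w.requires_grad or b.requires_grad,
        _parents=(x, w, b),
    )

    def _bw(g: np.ndarray) -> None:
        g2 = g.reshape(g.shape[0], g.shape[1], oh * ow)
        if w.requires_grad:
            dw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(w.shape))
        if b.requires_grad:
            b._accum(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, oh, ow))

    out._backward = _bw
    return out


# -------------------------------------------------------------- feature_affine
def feature_affine(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Per-feature affine map: (B,F,D) x (F,D,E) + (F,E) -> (B,F,E).

    Each feature index f carries its own weight matrix — the FET's
    "learnable fully connected layer per feature vector".
    """
    out_val = np.einsum("bfd,fde->bfe", x.data, w.data) + b.data[None]
    out = Tensor(
        out_val,
        requires_grad=x.requires_grad or w.requires_grad or b.requires_grad,
        _parents=(x, w, b),
    )

    def _bw(g: np.ndarray) -> None:
        if x.requires_grad:
            x._accum(np.einsum("bfe,fde->bfd", g, w.data))
        if w.requires_grad:
            w._accum(np.einsum("bfd,bfe->fde", x.data, g))
        if b.requires_grad:
            b._accum(g.sum(axis=0))

    out._backward = _bw
    return out


# ------------------------------------------------------------ stable BCE loss
def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    # log(1+e^z) = max(z,0) + log1p(e^{-|z|})
    loss_el = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss_el.mean(), requires_grad=logits.requires_grad, _parents=(logits,))

    def _bw(g: np.ndarray) -> None:
        if logits.requires_grad:
            p = np.where(
                z >= 0,
                1.0 / (1.0 + np.exp(-np.clip(z, 0, None))),
                np.exp(np.clip(z, None, 0)) / (1.0 + np.exp(np.clip(z, None, 0))),
            )
            logits._accum(g * (p - y) / y.size)

    out._backward = _bw
    return out
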