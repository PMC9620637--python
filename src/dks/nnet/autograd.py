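"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and remembers the operation that produced
it; calling :meth:`Tensor.backward` walks the tape in reverse topological
order and accumulates gradients into every tensor with ``requires_grad``.
Only the operations the keypoint networks need are provided: same-padding
convolution, 2x2 max pooling, nearest-neighbour upsampling, ReLU, sigmoid,
channel concatenation, affine layers, global average pooling and mean-squared
error.  Dtype follows the inputs, so float64 can be used for numerical
gradient checks while training runs in float32.

Convolution uses im2col: the padded input is exposed as a sliding-window
view, flattened to a (N*H*W, C*kh*kw) matrix and multiplied against the
flattened kernels; the backward pass reuses the same column matrix for the
weight gradient and scatters the input gradient with kh*kw shifted
slice-adds.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "scale",
    "relu",
    "sigmoid",
    "conv2d",
    "maxpool2",
    "upsample",
    "concat",
    "linear",
    "global_avg_pool",
    "mse",
    "add_scalars",
]


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep (stacked hourglasses)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self._accumulate(
            np.ones_like(self.data) if grad is None else np.asarray(grad)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, c: float) -> "Tensor":
        return scale(self, c)

    __rmul__ = __mul__


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _make(data, parents, backward) -> Tensor:
    needs = any(p.requires_grad for p in parents)
    return Tensor(data, parents=parents, backward=backward if needs else None)


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch {a.data.shape} vs {b.data.shape}")

    def backward(g):
        if a.requires_grad:
            a._accumulate(g)
        if b.requires_grad:
            b._accumulate(g)

    return _make(out_data, (a, b), backward)


def scale(a: Tensor, c: float) -> Tensor:
    c = float(c)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * c)

    return _make(a.data * c, (a,), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padding stride-1 convolution; w is (F, C, kh, kw), kh/kw odd."""
    n, c, h, wd = x.data.shape
    f, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {cw}")
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    else:
        xp = x.data
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # n,c,h,w,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h * wd, c * kh * kw
    )
    wm = w.data.reshape(f, -1)
    out_data = (cols @ wm.T + b.data).reshape(n, h, wd, f).transpose(0, 3, 1, 2)

    def backward(g):
        gf = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * wd, f)
        if w.requires_grad:
            w._accumulate((gf.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b._accumulate(gf.sum(axis=0))
        if x.requires_grad:
            dcols = (gf @ wm).reshape(n, h, wd, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + h, j : j + wd] += dcols[:, :, :, :, i, j]
            x._accumulate(dxp[:, :, ph : ph + h, pw : pw + wd] if (ph or pw) else dxp)

    return _make(out_data, (x, w, b), backward)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    arg = np.argmax(flat, axis=-1)
    out_data = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dx = (
            dflat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accumulate(dx)

    return _make(out_data, (x,), backward)


def upsample(x: Tensor, k: int) -> Tensor:
    """Nearest-neighbour upsampling by an integer factor."""
    k = int(k)
    out_data = np.repeat(np.repeat(x.data, k, axis=2), k, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = x.data.shape
            x._accumulate(
                g.reshape(n, c, h, k, w, k).sum(axis=(3, 5))
            )

    return _make(out_data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    out_data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(ts), backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Affine map: (N, Din) @ (Din, Dout) + (Dout,)."""
    out_data = x.data @ w.data + b.data

    def backward(g):
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))
        if x.requires_grad:
            x._accumulate(g @ w.data.T)

    return _make(out_data, (x, w, b), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    n, c, h, w = x.data.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x._accumulate(
                np.broadcast_to(g[:, :, None, None], x.data.shape) / (h * w)
            )

    return _make(out_data, (x,), backward)


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Scalar mean squared error against a constant target array."""
    target = np.asarray(target)
    if pred.data.shape != target.shape:
        raise ValueError(
            f"mse shape mismatch {pred.data.shape} vs {target.shape}"
        )
    diff = pred.data - target
    out_data = np.asarray((diff**2).mean(), dtype=pred.data.dtype)

    def backward(g):
        if pred.requires_grad:
            pred._accumulate((2.0 / diff.size) * diff * g)

    return _make(out_data, (pred,), backward)


def add_scalars(terms: Iterable[Tensor]) -> Tensor:
    """Sum of scalar tensors (loss aggregation)."""
    ts = list(terms)
    out_data = np.asarray(sum(float(t.data) for t in ts), dtype=ts[0].data.dtype)

    def backward(g):
        for t in ts:
            if t.requires_grad:
                t._accumulate(np.asarray(g, dtype=t.data.dtype))

    return _make(out_data, tuple(ts), backward)
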