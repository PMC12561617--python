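"""Reverse-mode automatic differentiation on numpy arrays.

A small, explicit tape: every operation returns a :class:`Tensor` that
remembers its parents and a closure computing the parent gradients from the
output gradient.  ``Tensor.backward()`` topologically sorts the graph and
accumulates ``.grad`` on every node it visits, which makes intermediate
activation gradients (needed for Grad-CAM) available for free.

All data is kept in float64.  Shapes follow the NCHW convention for image
batches.  Only the operations the classifier needs are implemented; each
backward rule is validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._bw = None

    # -- construction helper -------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: tuple["Tensor", ...], bw) -> "Tensor":
        out = Tensor(data)
        out._parents = parents
        out._bw = bw
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.grad is not None else 'no'})"

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; the graphs here can be a few thousand nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._bw is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._bw(node.grad)):
                if pgrad is None:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad.copy()
                else:
                    parent.grad = parent.grad + pgrad

    # -- elementwise arithmetic ----------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data
        sh_a, sh_b = self.data.shape, other.data.shape
        return Tensor._op(out_data, (self, other),
                          lambda g: (_unbroadcast(g, sh_a), _unbroadcast(g, sh_b)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        return Tensor._op(a * b, (self, other),
                          lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        return Tensor._op(a / b, (self, other),
                          lambda g: (_unbroadcast(g / b, a.shape),
                                     _unbroadcast(-g * a / (b * b), b.shape)))

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        a = self.data
        return Tensor._op(a ** p, (self,), lambda g: (g * p * a ** (p - 1),))

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._op(out, (self,), lambda g: (g * out,))

    def log(self):
        a = self.data
        return Tensor._op(np.log(a), (self,), lambda g: (g / a,))

    def sqrt(self):
        out = np.sqrt(self.data)
        # subgradient 0 at exactly zero (norms/variances of all-zero maps)
        safe = np.where(out > 0, out, 1.0)
        return Tensor._op(out, (self,),
                          lambda g: (np.where(out > 0, g * 0.5 / safe, 0.0),))

    def relu(self):
        a = self.data
        mask = a > 0
        return Tensor._op(a * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._op(out, (self,), lambda g: (g * out * (1.0 - out),))

    def clip_min(self, lo: float):
        """Elementwise max(x, lo); subgradient passes where x > lo."""
        a = self.data
        mask = a > lo
        return Tensor._op(np.maximum(a, lo), (self,), lambda g: (g * mask,))

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self.data
        out = a.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, a.shape).copy(),)

        return Tensor._op(out, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def _extremum(self, axis: int, keepdims: bool, fn):
        a = self.data
        out = fn(a, axis=axis, keepdims=True)
        mask = (a == out)
        count = mask.sum(axis=axis, keepdims=True)
        res = out if keepdims else np.squeeze(out, axis=axis)

        def bw(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            return (mask * (gg / count),)

        return Tensor._op(res, (self,), bw)

    def max(self, axis: int, keepdims: bool = False):
        return self._extremum(axis, keepdims, np.max)

    def min(self, axis: int, keepdims: bool = False):
        return self._extremum(axis, keepdims, np.min)

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        a_shape = self.data.shape
        return Tensor._op(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(a_shape),))

    def transpose2d(self):
        if self.data.ndim != 2:
            raise ValueError("transpose2d expects a 2D tensor")
        return Tensor._op(self.data.T, (self,), lambda g: (g.T,))

    # -- linear algebra ------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._wrap(other)
        a, b = self.data, other.data
        return Tensor._op(a @ b, (self, other),
                          lambda g: (g @ b.T, a.T @ g))

    __matmul__ = matmul


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer.  ``requires_grad`` may be set to
    False to freeze it (the optimizer then skips it)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# convolution / pooling functional ops
# ---------------------------------------------------------------------------

def same_padding(k: int) -> tuple[int, int]:
    """Asymmetric zero padding (before, after) preserving length for stride-1
    convolution with kernel size `k` (even sizes pad one more on the
    trailing side)."""
    return (k - 1) // 2, k - 1 - (k - 1) // 2


def _pad_nchw(x: np.ndarray, pt, pb, pl, pr) -> np.ndarray:
    if pt == pb == pl == pr == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding="same") -> Tensor:
    """Stride-1 2D convolution (cross-correlation), NCHW.

    ``w`` has shape (Cout, Cin, Kh, Kw); ``padding`` is "same", "valid" or an
    explicit (top, bottom, left, right) tuple.
    """
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"input has {cin} channels, kernel expects {cin_w}")
    if padding == "same":
        (pt, pb), (pl, pr) = same_padding(kh), same_padding(kw)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:
        pt, pb, pl, pr = padding
    xp = _pad_nchw(x.data, pt, pb, pl, pr)
    ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"spatial size {h}x{wd} too small for kernel {kh}x{kw}")
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (n,cin,ho,wo,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = (cols @ wmat.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
        dw = (gmat.T @ cols).reshape(cout, cin, kh, kw)
        dxp = np.zeros_like(xp)
        gq = gmat  # (n*ho*wo, cout)
        for i in range(kh):
            for j in range(kw):
                contrib = (gq @ wmat[:, :].reshape(cout, cin, kh, kw)[:, :, i, j])  # (n*ho*wo, cin)
                dxp[:, :, i:i + ho, j:j + wo] += contrib.reshape(n, ho, wo, cin).transpose(0, 3, 1, 2)
        dx = dxp[:, :, pt:pt + h, pl:pl + wd]
        grads = [dx, dw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._op(out, parents, bw)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding="same") -> Tensor:
    """Per-channel stride-1 convolution; ``w`` has shape (C, Kh, Kw)."""
    n, c, h, wd = x.data.shape
    cw, kh, kw = w.data.shape
    if c != cw:
        raise ValueError(f"input has {c} channels, depthwise kernel has {cw}")
    if padding == "same":
        (pt, pb), (pl, pr) = same_padding(kh), same_padding(kw)
    elif padding == "valid":
        pt = pb = pl = pr = 0
    else:
        pt, pb, pl, pr = padding
    xp = _pad_nchw(x.data, pt, pb, pl, pr)
    ho, wo = xp.shape[2] - kh + 1, xp.shape[3] - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (n,c,ho,wo,kh,kw)
    out = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        dw = np.einsum("nchwij,nchw->cij", win, g, optimize=True)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + ho, j:j + wo] += g * w.data[None, :, i, j, None, None]
        dx = dxp[:, :, pt:pt + h, pl:pl + wd]
        grads = [dx, dw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._op(out, parents, bw)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 (spatial dims must be even)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d requires even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    xr = x.data.reshape(n, c, ho, 2, wo, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    count = mask.sum(axis=(3, 5), keepdims=True)

    def bw(g):
        gg = g[:, :, :, None, :, None] / count
        return ((mask * gg).reshape(n, c, h, w),)

    return Tensor._op(out, (x,), bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw class scores."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean()

    def bw(g):
        dz = p.copy()
        dz[np.arange(n), labels] -= 1.0
        return (g * dz / n,)

    return Tensor._op(np.float64(nll), (logits,), bw)
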