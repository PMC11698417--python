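"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the dual-branch segmentation
network: elementwise arithmetic with broadcasting, matmul, reductions,
2-D convolution (stride 1, 'same' zero padding), 2x2 max pooling and
factor-2 bilinear upsampling. Gradients are accumulated into ``.grad``
by :meth:`Tensor.backward` in reverse topological order.

Dtype follows the input arrays; float64 inputs give float64 gradients,
which the finite-difference tests rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "concat", "conv2d", "maxpool2x2", "upsample2x",
    "relu", "sigmoid", "tanh", "exp", "log", "sqrt", "softmax", "clip",
]


def _as_array(x, like=None):
    if isinstance(x, np.ndarray):
        return x
    dtype = like.dtype if like is not None else np.float64
    return np.asarray(x, dtype=dtype)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- construction of derived nodes ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        # grads are never mutated in place, so storing the reference is safe
        if self.grad is None:
            self.grad = np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(_as_array(other, self.data))
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def amax(self, axis, keepdims=False):
        """Max over axes; ties split the gradient equally."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data)
        mask = mask / mask.sum(axis=axis, keepdims=True)
        res = out_data if keepdims else out_data.squeeze(axis)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(gg * mask)

        return Tensor._make(res, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- backprop driver ---------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() expects a scalar loss tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
                # free intermediate grads to bound memory; keep leaves
                if t is not self and t._parents:
                    t.grad = None

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


# -- elementwise nonlinearities -------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    with np.errstate(over="ignore"):   # saturates cleanly to 0/1
        s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return Tensor._make(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    return Tensor._make(t, (x,), backward)


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * e)

    return Tensor._make(e, (x,), backward)


def log(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accum(g / x.data)

    return Tensor._make(np.log(x.data), (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * 0.5 / r)

    return Tensor._make(r, (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only where the clamp is inactive."""
    mask = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(np.clip(x.data, lo, hi), (x,), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    """Numerically stable softmax along ``axis`` (shift is a constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


# -- spatial operators -----------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """2-D convolution, stride 1, zero 'same' padding for odd kernels.

    weight: (Cout, Cin, kh, kw); bias: (Cout,) or None.  Implemented as a
    sum of per-offset GEMMs (shift-and-multiply), which beats an explicit
    im2col patch matrix on CPU for the small channel counts used here.
    The channel-first padded input is kept for the backward pass.
    """
    n, c, h, w = x.data.shape
    cout, cin, kh, kw = weight.data.shape
    if cin != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cin}")
    pad = kh // 2
    if kh == 1 and kw == 1:
        wmat = weight.data.reshape(cout, c)
        xm = x.data.reshape(n, c, h * w)
        out = np.einsum("oc,nci->noi", wmat, xm, optimize=True)
        out = out.reshape(n, cout, h, w)
        if bias is not None:
            out += bias.data.reshape(1, cout, 1, 1)
        xpT = None
    else:
        xpT = np.pad(np.ascontiguousarray(x.data.transpose(1, 0, 2, 3)),
                     ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        acc = np.zeros((cout, n * h * w), dtype=x.data.dtype)
        for i in range(kh):
            for j in range(kw):
                sl = np.ascontiguousarray(
                    xpT[:, :, i:i + h, j:j + w]).reshape(c, -1)
                acc += weight.data[:, :, i, j] @ sl
        if bias is not None:
            acc += bias.data[:, None].astype(acc.dtype)
        out = np.ascontiguousarray(
            acc.reshape(cout, n, h, w).transpose(1, 0, 2, 3))
        if not (x.requires_grad or weight.requires_grad):
            xpT = None  # inference: nothing to keep

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if kh == 1 and kw == 1:
            gm = g.reshape(n, cout, h * w)
            if bias is not None and bias.requires_grad:
                bias._accum(gm.sum(axis=(0, 2)))
            if weight.requires_grad:
                xm = x.data.reshape(n, c, h * w)
                dw = np.einsum("noi,nci->oc", gm, xm, optimize=True)
                weight._accum(dw.reshape(weight.data.shape))
            if x.requires_grad:
                wmat = weight.data.reshape(cout, c)
                dx = np.einsum("oc,noi->nci", wmat, gm, optimize=True)
                x._accum(dx.reshape(n, c, h, w))
            return
        g2d = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(cout, -1)
        if bias is not None and bias.requires_grad:
            bias._accum(g2d.sum(axis=1))
        need_w = weight.requires_grad
        need_x = x.requires_grad
        if not (need_w or need_x):
            return
        dw = np.empty_like(weight.data) if need_w else None
        hp, wp = h + 2 * pad, w + 2 * pad
        dxT = np.zeros((c, n, hp, wp), dtype=g.dtype) if need_x else None
        for i in range(kh):
            for j in range(kw):
                if need_w:
                    sl = np.ascontiguousarray(
                        xpT[:, :, i:i + h, j:j + w]).reshape(c, -1)
                    dw[:, :, i, j] = g2d @ sl.T
                if need_x:
                    dxT[:, :, i:i + h, j:j + w] += (
                        weight.data[:, :, i, j].T @ g2d).reshape(c, n, h, w)
        if need_w:
            weight._accum(dw)
        if need_x:
            if pad:
                dxT = dxT[:, :, pad:pad + h, pad:pad + w]
            x._accum(np.ascontiguousarray(dxT.transpose(1, 0, 2, 3)))

    return Tensor._make(out, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 needs even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    arg = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(gr, arg[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gr.reshape(n, c, h, w))

    return Tensor._make(out, (x,), backward)


def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
    # factor-2 bilinear along one axis, half-pixel centers (align_corners=False)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    out = np.empty(x.shape[:-1] + (2 * n,), dtype=x.dtype)
    out[..., 0] = x[..., 0]
    out[..., -1] = x[..., -1]
    if n > 1:
        out[..., 2:-1:2] = 0.25 * x[..., :-1] + 0.75 * x[..., 1:]
        out[..., 1:-1:2] = 0.75 * x[..., :-1] + 0.25 * x[..., 1:]
    return np.moveaxis(out, -1, axis)


def _up1d_adj(g: np.ndarray, axis: int) -> np.ndarray:
    # adjoint of _up1d
    g = np.moveaxis(g, axis, -1)
    n = g.shape[-1] // 2
    out = np.zeros(g.shape[:-1] + (n,), dtype=g.dtype)
    out[..., 0] += g[..., 0]
    out[..., -1] += g[..., -1]
    if n > 1:
        out[..., :-1] += 0.25 * g[..., 2:-1:2] + 0.75 * g[..., 1:-1:2]
        out[..., 1:] += 0.75 * g[..., 2:-1:2] + 0.25 * g[..., 1:-1:2]
    return np.moveaxis(out, -1, axis)


def upsample2x(x: Tensor) -> Tensor:
    """Factor-2 bilinear upsampling of an (N,C,H,W) tensor."""
    out = _up1d(_up1d(x.data, 2), 3)

    def backward(g):
        if x.requires_grad:
            x._accum(_up1d_adj(_up1d_adj(g, 3), 2))

    return Tensor._make(out, (x,), backward)
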