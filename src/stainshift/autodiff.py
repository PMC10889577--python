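"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Implements exactly the operator set the stain-transfer networks need:
broadcasted arithmetic, matmul, 2-D convolution (im2col), nearest-neighbour
upsampling, zero-fill spatial shifts (for the guided filters), softmax,
elementwise nonlinearities, reductions and a fused mean-Huber loss.

Gradients accumulate into ``Tensor.grad``. A ``grad_hook`` set on a tensor is
applied to its fully-accumulated gradient before it propagates to parents;
the training loop uses this to gate generator gradients with discriminator
saliency maps.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "grad_hook")

    def __init__(self, data, requires_grad: bool = False):
        a = np.asarray(data)
        if a.dtype not in (np.float32, np.float64):
            a = a.astype(np.float32)
        self.data = a
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()
        self.grad_hook = None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)
        # iterative topological sort (graphs can be deep)
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        _accum(self, grad)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            if node.grad_hook is not None:
                node.grad = node.grad_hook(node.grad)
            node._backward()

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_t(other)))

    def __rsub__(self, other):
        return add(_t(other), neg(self))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_t(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)


def _t(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, (int, float)):
        # python scalars join the graph at float32 so they do not promote
        # float32 networks to float64 (float64 graphs still win promotion)
        return Tensor(np.float32(x))
    return Tensor(x)


def _track(*tensors) -> bool:
    return _grad_enabled and any(t.requires_grad for t in tensors)


def _attach(out: Tensor, parents, backward):
    out.requires_grad = True
    out._parents = tuple(parents)
    out._backward = backward


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    if g.shape == tuple(shape):
        return g
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _accum(t: Tensor, g):
    if not t.requires_grad:
        return
    g = _unbroadcast(np.asarray(g), t.data.shape)
    # gradients are never mutated in place, so sharing the incoming array is safe
    t.grad = g if t.grad is None else t.grad + g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = _t(a), _t(b)
    out = Tensor(a.data + b.data)
    if _track(a, b):
        def bw():
            _accum(a, out.grad)
            _accum(b, out.grad)
        _attach(out, (a, b), bw)
    return out


def mul(a, b):
    a, b = _t(a), _t(b)
    out = Tensor(a.data * b.data)
    if _track(a, b):
        def bw():
            _accum(a, out.grad * b.data)
            _accum(b, out.grad * a.data)
        _attach(out, (a, b), bw)
    return out


def neg(a):
    a = _t(a)
    out = Tensor(-a.data)
    if _track(a):
        def bw():
            _accum(a, -out.grad)
        _attach(out, (a,), bw)
    return out


def div(a, b):
    a, b = _t(a), _t(b)
    out = Tensor(a.data / b.data)
    if _track(a, b):
        def bw():
            _accum(a, out.grad / b.data)
            _accum(b, -out.grad * a.data / (b.data * b.data))
        _attach(out, (a, b), bw)
    return out


def power(a, p: float):
    a = _t(a)
    out = Tensor(a.data ** p)
    if _track(a):
        def bw():
            _accum(a, out.grad * p * a.data ** (p - 1.0))
        _attach(out, (a,), bw)
    return out


def exp(a):
    a = _t(a)
    out = Tensor(np.exp(a.data))
    if _track(a):
        def bw():
            _accum(a, out.grad * out.data)
        _attach(out, (a,), bw)
    return out


def tanh(a):
    a = _t(a)
    out = Tensor(np.tanh(a.data))
    if _track(a):
        def bw():
            _accum(a, out.grad * (1.0 - out.data * out.data))
        _attach(out, (a,), bw)
    return out


def leaky_relu(a, slope: float = 0.2):
    a = _t(a)
    pos = a.data > 0
    out = Tensor(np.where(pos, a.data, slope * a.data))
    if _track(a):
        def bw():
            _accum(a, out.grad * np.where(pos, 1.0, slope))
        _attach(out, (a,), bw)
    return out


def relu(a):
    return leaky_relu(a, 0.0)


def abs_(a):
    a = _t(a)
    out = Tensor(np.abs(a.data))
    if _track(a):
        def bw():
            _accum(a, out.grad * np.sign(a.data))
        _attach(out, (a,), bw)
    return out


# ---------------------------------------------------------------------------
# reductions & shape
# ---------------------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = _t(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims))
    if _track(a):
        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                shape = list(a.data.shape)
                for ax in axes:
                    shape[ax % a.data.ndim] = 1
                g = g.reshape(shape)
            _accum(a, np.broadcast_to(g, a.data.shape))
        _attach(out, (a,), bw)
    return out


def mean(a, axis=None, keepdims=False):
    a = _t(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax % a.data.ndim] for ax in axes]))
    return sum_(a, axis, keepdims) * (1.0 / n)


def reshape(a, shape):
    a = _t(a)
    out = Tensor(a.data.reshape(shape))
    if _track(a):
        def bw():
            _accum(a, out.grad.reshape(a.data.shape))
        _attach(out, (a,), bw)
    return out


def transpose(a, axes):
    a = _t(a)
    out = Tensor(a.data.transpose(axes))
    if _track(a):
        inv = tuple(np.argsort(axes))

        def bw():
            _accum(a, out.grad.transpose(inv))
        _attach(out, (a,), bw)
    return out


def concat(tensors, axis=0):
    tensors = [_t(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _track(*tensors):
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw():
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                _accum(t, g)
        _attach(out, tuple(tensors), bw)
    return out


def matmul(a, b):
    a, b = _t(a), _t(b)
    out = Tensor(np.matmul(a.data, b.data))
    if _track(a, b):
        def bw():
            g = out.grad
            if a.data.ndim == 1 or b.data.ndim == 1:
                raise NotImplementedError("matmul backward requires >=2-D operands")
            _accum(a, np.matmul(g, np.swapaxes(b.data, -1, -2)))
            _accum(b, np.matmul(np.swapaxes(a.data, -1, -2), g))
        _attach(out, (a, b), bw)
    return out


def softmax(a, axis=-1):
    a = _t(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s)
    if _track(a):
        def bw():
            g = out.grad
            _accum(a, (g - (g * s).sum(axis=axis, keepdims=True)) * s)
        _attach(out, (a,), bw)
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def huber_mean(a, b, delta: float = 1.0):
    """Mean elementwise Huber loss between two equal-shape tensors."""
    a, b = _t(a), _t(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch {a.data.shape} vs {b.data.shape}")
    d = a.data - b.data
    ad = np.abs(d)
    quad = ad <= delta
    vals = np.where(quad, 0.5 * d * d, delta * (ad - 0.5 * delta))
    out = Tensor(vals.mean())
    if _track(a, b):
        def bw():
            dd = np.clip(d, -delta, delta) * (out.grad / d.size)
            _accum(a, dd)
            _accum(b, -dd)
        _attach(out, (a, b), bw)
    return out


def l1_mean(a, b):
    a, b = _t(a), _t(b)
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch {a.data.shape} vs {b.data.shape}")
    return mean(abs_(a - b))


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D convolution (cross-correlation) on NCHW input.

    x: [B,C,H,W]; w: [O,C,kh,kw]; b: [O] or None.
    """
    x, w = _t(x), _t(w)
    if b is not None:
        b = _t(b)
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # [B,C,Ho,Wo,kh,kw] -> [B, Ho*Wo, C*kh*kw]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B, Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(O, C * kh * kw)
    out_d = cols @ wmat.T  # [B, Ho*Wo, O]
    if b is not None:
        out_d = out_d + b.data
    out = Tensor(out_d.transpose(0, 2, 1).reshape(B, O, Ho, Wo))
    parents = (x, w) if b is None else (x, w, b)
    if _track(*parents):
        def bw():
            g = out.grad.reshape(B, O, Ho * Wo).transpose(0, 2, 1)  # [B,HoWo,O]
            if w.requires_grad:
                dw = np.einsum("bno,bnk->ok", g, cols)
                _accum(w, dw.reshape(O, C, kh, kw))
            if b is not None and b.requires_grad:
                _accum(b, g.sum(axis=(0, 1)))
            if x.requires_grad:
                dcols = g @ wmat  # [B,HoWo,C*kh*kw]
                dc = dcols.reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                dxp = np.zeros((B, C, Hp, Wp), dtype=x.data.dtype)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dc[:, :, :, :, i, j]
                _accum(x, dxp[:, :, p:Hp - p or None, p:Wp - p or None] if p else dxp)
        _attach(out, parents, bw)
    return out


def upsample2x(x):
    """Nearest-neighbour 2x upsampling of NCHW input."""
    x = _t(x)
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3))
    if _track(x):
        B, C, H, W = x.data.shape

        def bw():
            _accum(x, out.grad.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))
        _attach(out, (x,), bw)
    return out


def shift2d(x, dy: int, dx: int):
    """Zero-fill spatial shift: out[..., i, j] = x[..., i+dy, j+dx] where valid."""
    x = _t(x)
    H, W = x.data.shape[-2:]
    ys_dst = slice(max(-dy, 0), H - max(dy, 0) or None)
    ys_src = slice(max(dy, 0), H - max(-dy, 0) or None)
    xs_dst = slice(max(-dx, 0), W - max(dx, 0) or None)
    xs_src = slice(max(dx, 0), W - max(-dx, 0) or None)
    data = np.zeros_like(x.data)
    data[..., ys_dst, xs_dst] = x.data[..., ys_src, xs_src]
    out = Tensor(data)
    if _track(x):
        def bw():
            g = np.zeros_like(x.data)
            g[..., ys_src, xs_src] = out.grad[..., ys_dst, xs_dst]
            _accum(x, g)
        _attach(out, (x,), bw)
    return out


def shift2d_valid_mask(shape_hw, dy: int, dx: int, dtype=np.float32) -> np.ndarray:
    """Constant validity mask matching shift2d's zero-filled border."""
    H, W = shape_hw
    m = np.zeros((H, W), dtype=dtype)
    ys = slice(max(-dy, 0), H - max(dy, 0) or None)
    xs = slice(max(-dx, 0), W - max(dx, 0) or None)
    m[ys, xs] = 1.0
    return m
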