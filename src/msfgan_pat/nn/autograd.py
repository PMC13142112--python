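"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine in the style of the familiar deep-learning
frameworks, sized for the networks in this package.  Every primitive's
vector-Jacobian product is itself expressed through primitives, so
gradients can be differentiated again (``create_graph=True``); this is
what the R1/R2 gradient penalties on the discriminator require, since
they penalize the squared norm of an input gradient and must themselves
be differentiated with respect to the discriminator parameters.

Conventions
-----------
* Image batches are NCHW.
* Convolution is cross-correlation (no kernel flip), as in every
  deep-learning framework.
* dtype follows the inputs; float32 is used throughout the networks,
  float64 in the numerical-gradient tests.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.special import expit

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "grad",
    "concat",
    "corr2d",
    "pad2d",
    "dilate2d",
    "flip_kernel2d",
    "bilinear_upsample2x",
    "pixel_shuffle",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording inside the context."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "parents", "_vjp", "requires_grad", "grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), vjp: Callable | None = None):
        if type(data) is not np.ndarray:
            if isinstance(data, Tensor):
                data = data.data
            else:
                data = np.asarray(data)
        if data.dtype.kind != "f":
            data = data.astype(np.float32)
        self.data = data
        self.parents = parents
        self._vjp = vjp
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_as_tensor(other), power(self, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return tmax(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def backward(self, grad_output=None, free_graph: bool = True):
        """Accumulate gradients into ``.grad`` of every reachable leaf.

        With ``free_graph`` (the default) the tape is released
        immediately afterwards: vjp closures reference their output
        node, so graphs form reference cycles that would otherwise wait
        for the cyclic collector while holding large activations.
        """
        topo, leaves = _toposort(self)
        grads = grad(self, leaves, grad_output=grad_output,
                     create_graph=False, _topo=topo)
        for leaf, g in zip(leaves, grads):
            if leaf.grad is None:
                leaf.grad = g.data.copy()
            else:
                leaf.grad = leaf.grad + g.data
        if free_graph:
            for node in topo:
                if node.parents:
                    node.parents = ()
                    node._vjp = None


def _as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, (int, float)):
        # keep python scalars weak (float32 nets must not upcast)
        return Tensor(np.float32(x))
    return Tensor(np.asarray(x))


def _make(data, parents, vjp) -> Tensor:
    """Create an op result; record the tape only when grads are on."""
    if is_grad_enabled() and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, vjp=vjp)
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        return _sum_to(g, a.shape), _sum_to(g, b.shape)

    return _make(a.data + b.data, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        return _sum_to(mul(g, b), a.shape), _sum_to(mul(g, a), b.shape)

    return _make(a.data * b.data, (a, b), vjp)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    exponent = float(exponent)

    def vjp(g):
        return (mul(g, mul(power(a, exponent - 1.0), exponent)),)

    return _make(a.data ** exponent, (a,), vjp)


def texp(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def vjp(g):
        return (mul(g, out),)

    out = _make(out_data, (a,), vjp)
    return out


def tlog(a) -> Tensor:
    a = _as_tensor(a)

    def vjp(g):
        return (mul(g, power(a, -1.0)),)

    return _make(np.log(a.data), (a,), vjp)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    out_data = expit(a.data)

    def vjp(g):
        return (mul(g, mul(out, add(1.0, -out))),)

    out = _make(out_data, (a,), vjp)
    return out


def softplus(a) -> Tensor:
    """log(1 + exp(a)), numerically stable."""
    a = _as_tensor(a)

    def vjp(g):
        return (mul(g, sigmoid(a)),)

    return _make(np.logaddexp(0.0, a.data), (a,), vjp)


def relu(a) -> Tensor:
    a = _as_tensor(a)

    def vjp(g):
        mask = (a.data > 0).astype(a.data.dtype)
        return (mul(g, mask),)

    return _make(np.maximum(a.data, 0), (a,), vjp)


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    s = a.data.dtype.type(slope)

    def vjp(g):
        scale = np.where(a.data > 0, a.data.dtype.type(1), s)
        return (mul(g, scale),)

    return _make(np.where(a.data > 0, a.data, s * a.data), (a,), vjp)


def prelu(a, slope: Tensor) -> Tensor:
    """PReLU with a learnable (per-channel or scalar) negative slope."""
    pos = relu(a)
    return pos + mul(slope, a - pos)


# ---------------------------------------------------------------------------
# reductions and shape ops
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    axes = axis if axis is None or isinstance(axis, tuple) else (axis,)

    def vjp(g):
        if axes is not None and not keepdims:
            shape = list(a.shape)
            for ax in axes:
                shape[ax] = 1
            g = reshape(g, tuple(shape))
        return (broadcast_to(g, a.shape),)

    return _make(out_data, (a,), vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def tmax(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.max(axis=axis, keepdims=keepdims)
    full = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == full)
    mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties evenly
    mask = mask.astype(a.data.dtype)
    axes = axis if axis is None or isinstance(axis, tuple) else (axis,)

    def vjp(g):
        if axes is not None and not keepdims:
            shape = list(a.shape)
            for ax in axes:
                shape[ax] = 1
            g = reshape(g, tuple(shape))
        return (mul(broadcast_to(g, a.shape), mask),)

    return _make(out_data, (a,), vjp)


def broadcast_to(a, shape) -> Tensor:
    a = _as_tensor(a)
    shape = tuple(shape)
    if a.shape == shape:
        return a

    def vjp(g):
        return (_sum_to(g, a.shape),)

    return _make(np.broadcast_to(a.data, shape), (a,), vjp)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape

    def vjp(g):
        return (reshape(g, old),)

    return _make(a.data.reshape(shape), (a,), vjp)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def vjp(g):
        return (transpose(g, inv),)

    return _make(np.ascontiguousarray(a.data.transpose(axes)), (a,), vjp)


def getitem(a, key) -> Tensor:
    a = _as_tensor(a)

    def vjp(g):
        return (_unslice(g, a.shape, key),)

    return _make(a.data[key], (a,), vjp)


def _unslice(g, shape, key) -> Tensor:
    g = _as_tensor(g)

    def vjp(gg):
        return (getitem(gg, key),)

    out = np.zeros(shape, dtype=g.dtype)
    out[key] = g.data
    return _make(out, (g,), vjp)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        outs = []
        for i in range(len(tensors)):
            key = [slice(None)] * g.ndim
            key[axis] = slice(int(offsets[i]), int(offsets[i + 1]))
            outs.append(getitem(g, tuple(key)))
        return tuple(outs)

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), vjp)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)

    def vjp(g):
        ga = matmul(g, transpose(b, (1, 0)))
        gb = matmul(transpose(a, (1, 0)), g)
        return ga, gb

    return _make(a.data @ b.data, (a, b), vjp)


# ---------------------------------------------------------------------------
# structural image primitives
# ---------------------------------------------------------------------------

def pad2d(a, pads) -> Tensor:
    """Zero-pad the last two axes; ``pads`` = (top, bottom, left, right)."""
    a = _as_tensor(a)
    t, b, l, r = pads
    if t == b == l == r == 0:
        return a
    H, W = a.shape[-2:]

    def vjp(g):
        key = (Ellipsis, slice(t, t + H), slice(l, l + W))
        return (getitem(g, key),)

    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    return _make(np.pad(a.data, width), (a,), vjp)


def dilate2d(a, stride: int, out_hw) -> Tensor:
    """Insert ``stride-1`` zeros between entries of the last two axes.

    ``out_hw`` fixes the output spatial size (it may exceed the minimal
    dilated extent when a strided convolution did not tile its input
    exactly)."""
    a = _as_tensor(a)
    if stride == 1 and tuple(out_hw) == a.shape[-2:]:
        return a
    H, W = a.shape[-2:]
    oh, ow = out_hw
    key = (Ellipsis, slice(0, (H - 1) * stride + 1, stride),
           slice(0, (W - 1) * stride + 1, stride))

    def vjp(g):
        return (getitem(g, key),)

    out = np.zeros(a.shape[:-2] + (oh, ow), dtype=a.dtype)
    out[key] = a.data
    return _make(out, (a,), vjp)


def flip_kernel2d(w) -> Tensor:
    """Spatially flip a conv kernel and swap its in/out channel axes."""
    w = _as_tensor(w)

    def vjp(g):
        return (flip_kernel2d(g),)

    return _make(np.ascontiguousarray(
        w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)), (w,), vjp)


def corr2d(x, w, stride: int = 1, padding: int = 0) -> Tensor:
    """Batched 2-D cross-correlation: x (C,N,H,W) with w (Co,C,kh,kw).

    Features are channel-leading: the im2col matrix multiplies the
    flattened weight straight into the (Co, N*Ho*Wo) output, which is
    already the next feature map — no layout copies.  The
    vector-Jacobian products are the primitives ``corrT2d`` (input
    gradient) and ``conv_wgrad`` (weight gradient), and those close
    back over this family, so the op is differentiable to any order —
    the discriminator gradient penalties rely on that.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    C, N, H, W = x.shape
    Co, Ci, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, kernel {Ci}")
    if _direct_path(stride, C, Co, kh, W):
        from ._kernels import corr_direct
        y = corr_direct(x.data, w.data, padding)
        cols = None
    else:
        from ._kernels import im2col
        cols = im2col(x.data, kh, kw, stride, padding)
        Ho = (H + 2 * padding - kh) // stride + 1
        Wo = (W + 2 * padding - kw) // stride + 1
        y = (w.data.reshape(Co, -1) @ cols).reshape(Co, N, Ho, Wo)

    def vjp(g):
        gx = (corrT2d(g, w, stride, padding, (H, W))
              if x.requires_grad else None)
        gw = (conv_wgrad(x, g, stride, padding, kh, kw, _cols=cols)
              if w.requires_grad else None)
        return gx, gw

    return _make(y, (x, w), vjp)


def _direct_path(stride: int, C: int, Co: int, k: int, W: int) -> bool:
    """Prefer the direct loops when the im2col/outer-product matrices
    would dwarf the work, i.e. very few channels on either side (the
    1-channel image heads/tails); otherwise im2col + BLAS wins."""
    return stride == 1 and (Co <= 4 or C <= 4)


def corrT2d(g, w, stride: int, padding: int, out_hw) -> Tensor:
    """Transpose of ``corr2d(., w)`` applied to g (Co,N,Ho,Wo)."""
    g, w = _as_tensor(g), _as_tensor(w)
    Co, N = g.shape[:2]
    _, C, kh, kw = w.shape
    H, W = out_hw
    # mirror of the forward dispatch: C and Co swap transposed roles
    if _direct_path(stride, Co, C, kh, W):
        from ._kernels import corrT_direct
        out = corrT_direct(g.data, w.data, padding, H, W)
    else:
        from ._kernels import col2im
        cols_g = w.data.reshape(Co, -1).T @ g.data.reshape(Co, -1)
        out = col2im(cols_g, C, N, H, W, kh, kw, stride, padding)

    def vjp(d):
        dg = (corr2d(d, w, stride, padding) if g.requires_grad else None)
        dw = (conv_wgrad(d, g, stride, padding, kh, kw)
              if w.requires_grad else None)
        return dg, dw

    return _make(out, (g, w), vjp)


def conv_wgrad(x, g, stride: int, padding: int, kh: int, kw: int,
               _cols: np.ndarray | None = None) -> Tensor:
    """Gradient of ``corr2d(x, .)`` w.r.t. its kernel, as a primitive.

    Bilinear in (x, g); its own vjps are again members of the family.
    ``_cols`` may carry the im2col matrix cached by the forward pass.
    """
    x, g = _as_tensor(x), _as_tensor(g)
    C, N, H, W = x.shape
    Co = g.shape[0]
    if _cols is None and _direct_path(stride, C, Co, kh, W):
        from ._kernels import wgrad_direct
        gw = wgrad_direct(x.data, g.data, padding, kh, kw)
    else:
        if _cols is None:
            from ._kernels import im2col
            _cols = im2col(x.data, kh, kw, stride, padding)
        gw = (g.data.reshape(Co, -1) @ _cols.T).reshape(Co, C, kh, kw)

    def vjp(d):
        dx = (corrT2d(g, d, stride, padding, (H, W))
              if x.requires_grad else None)
        dg = (corr2d(x, d, stride, padding) if g.requires_grad else None)
        return dx, dg

    return _make(gw, (x, g), vjp)


def pixel_shuffle(x, r: int = 2) -> Tensor:
    """Depth-to-space: (C*r*r, N, H, W) -> (C, N, H*r, W*r).

    Channel block c*r*r + a*r + b maps to output offset (a, b)."""
    x = _as_tensor(x)
    Crr, N, H, W = x.shape
    if Crr % (r * r):
        raise ValueError(f"channels {Crr} not divisible by r^2={r * r}")
    C = Crr // (r * r)
    t = reshape(x, (C, r, r, N, H, W))
    t = transpose(t, (0, 3, 4, 1, 5, 2))
    return reshape(t, (C, N, H * r, W * r))


_BILINEAR_CACHE: dict = {}


def _bilinear_matrix(n: int, dtype) -> np.ndarray:
    """Interpolation matrix (2n, n) for x2 upsampling, align_corners=False."""
    key = (n, np.dtype(dtype).name)
    if key not in _BILINEAR_CACHE:
        M = np.zeros((2 * n, n), dtype=dtype)
        for i in range(2 * n):
            src = (i + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            frac = src - i0
            i0c = min(max(i0, 0), n - 1)
            i1c = min(max(i0 + 1, 0), n - 1)
            M[i, i0c] += 1.0 - frac
            M[i, i1c] += frac
        _BILINEAR_CACHE[key] = M
    return _BILINEAR_CACHE[key]


def bilinear_upsample2x(x) -> Tensor:
    """Bilinear x2 upsampling over the last two axes of a 4-D tensor,
    realized as two small interpolation matmuls."""
    x = _as_tensor(x)
    N, C, H, W = x.shape    # leading two axes are passed through
    Mh = Tensor(_bilinear_matrix(H, x.dtype))
    Mw = Tensor(_bilinear_matrix(W, x.dtype))
    t = reshape(transpose(x, (2, 0, 1, 3)), (H, N * C * W))
    t = matmul(Mh, t)                                    # (2H, N*C*W)
    t = transpose(reshape(t, (2 * H, N, C, W)), (3, 1, 2, 0))
    t = reshape(t, (W, N * C * 2 * H))
    t = matmul(Mw, t)                                    # (2W, N*C*2H)
    t = reshape(t, (2 * W, N, C, 2 * H))
    return transpose(t, (1, 2, 3, 0))


# ---------------------------------------------------------------------------
# backward engine
# ---------------------------------------------------------------------------

def _toposort(root: Tensor):
    """Topological order of the requires-grad subgraph; also the leaves."""
    order, leaves = [], []
    seen = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        if node.parents:
            for p in node.parents:
                stack.append((p, False))
        else:
            leaves.append(node)
    return order, leaves


def grad(output: Tensor, inputs: Sequence[Tensor], grad_output=None,
         create_graph: bool = False, _topo=None) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own tape
    and can be differentiated again.
    """
    topo = _toposort(output)[0] if _topo is None else _topo
    input_ids = {id(t) for t in inputs}
    if grad_output is None:
        grad_output = Tensor(np.ones(output.shape, dtype=output.dtype))
    gmap: dict[int, Tensor] = {id(output): _as_tensor(grad_output)}

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        for node in reversed(topo):
            g = gmap.get(id(node))
            if g is None or node._vjp is None:
                continue
            parent_grads = node._vjp(g)
            for p, pg in zip(node.parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                acc = gmap.get(id(p))
                gmap[id(p)] = pg if acc is None else add(acc, pg)
            if id(node) not in input_ids:
                del gmap[id(node)]

    out = []
    for t in inputs:
        g = gmap.get(id(t))
        if g is None:
            g = Tensor(np.zeros(t.shape, dtype=t.dtype))
        out.append(g)
    return out
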