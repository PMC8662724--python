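"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine providing exactly the primitives the
segmentation network needs: broadcast arithmetic, reductions, 3x3/1x1
convolution (im2col), 2x2 max/average pooling, bilinear resampling (expressed
as a separable linear operator so its adjoint is exact), channel
concatenation, and the activations used by the model (ReLU, PReLU, sigmoid,
softmax). Everything is float64 and single-threaded numpy, so runs are
bit-reproducible for a fixed seed.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which walks the recorded graph in reverse topological order. Each primitive
is validated against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

DTYPE = np.float64


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the graph bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- properties -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without an explicit gradient "
                                   "is only defined for scalar outputs")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other) -> "Tensor":
        return (-self) + other

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __pow__(self, exponent: float) -> "Tensor":
        exponent = float(exponent)
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __truediv__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor(other) * self ** -1.0

    def __matmul__(self, other: "Tensor") -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- reductions and shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy()
                                 if np.ndim(g) else np.full(self.shape, g))
                return
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                axes = tuple(a % self.ndim for a in axes)
                g = np.expand_dims(g, tuple(sorted(axes)))
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old_shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def log(self) -> "Tensor":
        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is passed through only inside [lo, hi]."""
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)


# ---------------------------------------------------------------------------
# Free-function primitives
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tensors, backward)


def prelu(x: Tensor, a: Tensor) -> Tensor:
    """Parametric ReLU max(0, x) + a * min(0, x) with learnable slope ``a``."""
    neg = np.minimum(x.data, 0.0)
    pos = np.maximum(x.data, 0.0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(x.data > 0, 1.0, a.data))
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * neg, a.shape))

    return Tensor._make(pos + a.data * neg, (x, a), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            x._accumulate(out_data * (g - inner))

    return Tensor._make(out_data, (x,), backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           padding: int = 0) -> Tensor:
    """Stride-1 2D convolution (cross-correlation) via im2col.

    ``x`` is (N, C, H, W); ``weight`` is (C_out, C_in, kh, kw).
    """
    xd, wd = x.data, weight.data
    n, c, h, w = xd.shape
    c_out, c_in, kh, kw = wd.shape
    if c != c_in:
        raise ValueError(f"conv2d channel mismatch: expected {c_in}, got {c}")
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    h_out = h + 2 * padding - kh + 1
    w_out = w + 2 * padding - kw + 1

    def im2col(arr):
        windows = np.lib.stride_tricks.sliding_window_view(
            arr, (kh, kw), axis=(2, 3))
        return windows.transpose(0, 2, 3, 1, 4, 5).reshape(
            n * h_out * w_out, c * kh * kw)

    # the column matrix is rebuilt in backward rather than kept alive in the
    # closure: it is k*k times larger than the activation itself
    cols = im2col(xp)
    out = cols @ wd.reshape(c_out, -1).T
    del cols
    if bias is not None:
        out = out + bias.data
    out = out.reshape(n, h_out, w_out, c_out).transpose(0, 3, 1, 2)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g_cols = g.transpose(0, 2, 3, 1).reshape(n * h_out * w_out, c_out)
        if weight.requires_grad:
            weight._accumulate((g_cols.T @ im2col(xp)).reshape(wd.shape))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g_cols.sum(axis=0))
        if x.requires_grad:
            g_patch = (g_cols @ wd.reshape(c_out, -1)).reshape(
                n, h_out, w_out, c, kh, kw)
            g_xp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    g_xp[:, :, i:i + h_out, j:j + w_out] += \
                        g_patch[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                g_xp = g_xp[:, :, padding:padding + h, padding:padding + w]
            x._accumulate(g_xp)

    return Tensor._make(out, parents, backward)


def max_pool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2 requires even spatial dims, got {h}x{w}")
    patches = x.data.reshape(n, c, h // 2, 2, w // 2, 2) \
                    .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = patches.argmax(axis=-1)
    out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        g_patches = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(g_patches, idx[..., None], g[..., None], axis=-1)
        g_x = g_patches.reshape(n, c, h // 2, w // 2, 2, 2) \
                       .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(g_x)

    return Tensor._make(out, (x,), backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 requires even spatial dims, got {h}x{w}")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            g_x = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accumulate(g_x)

    return Tensor._make(out, (x,), backward)


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D bilinear interpolation operator using half-pixel centers."""
    key = (n_in, n_out)
    cached = _INTERP_CACHE.get(key)
    if cached is not None:
        return cached
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for o in range(n_out):
        s = (o + 0.5) * scale - 0.5
        s = min(max(s, 0.0), n_in - 1.0)
        i0 = int(np.floor(s))
        i1 = min(i0 + 1, n_in - 1)
        frac = s - i0
        m[o, i0] += 1.0 - frac
        m[o, i1] += frac
    _INTERP_CACHE[key] = m
    return m


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resampling to (out_h, out_w).

    Implemented as R @ X @ C^T per image/channel, so the backward pass is the
    exact adjoint R^T @ G @ C. Resampling to the same size is the identity.
    """
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        def backward_id(g):
            if x.requires_grad:
                x._accumulate(g)

        return Tensor._make(x.data.copy(), (x,), backward_id)

    rows = _interp_matrix(h, out_h)
    cols = _interp_matrix(w, out_w)
    # (N,C,H,W) @ (W,Wout) -> rows step via einsum-free matmuls
    tmp = x.data @ cols.T                                     # N,C,H,Wout
    out = (tmp.transpose(0, 1, 3, 2) @ rows.T).transpose(0, 1, 3, 2)

    def backward(g):
        if x.requires_grad:
            t = (g.transpose(0, 1, 3, 2) @ rows).transpose(0, 1, 3, 2)
            x._accumulate(t @ cols)

    return Tensor._make(out, (x,), backward)


def stack_parameters(tensors: Iterable[Tensor]) -> list[Tensor]:
    return [t for t in tensors if t.requires_grad]
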