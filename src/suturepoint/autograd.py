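"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical core the detector is built on: a :class:`Tensor`
wrapping a float64 ``numpy.ndarray`` together with a dynamically recorded
computation graph, and the small set of differentiable primitives a U-Net
with custom heatmap layers needs (broadcast arithmetic, matmul, reshape /
transpose, relu / sigmoid / exp, axis reductions, concatenation, 2x2 max
pooling, and a stride-1 sliding-window ``unfold`` with zero or reflect
padding that backs the convolution, Gaussian-filter and soft-argmax layers).

Gradients are accumulated by a topological-order backward sweep.  Everything
is float64: the engine favours numerical transparency (finite-difference
checkable to tight tolerances) over raw speed, which is adequate at the
image sizes this package trains at.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "parameter",
    "add",
    "mul",
    "matmul",
    "reshape",
    "transpose",
    "relu",
    "sigmoid",
    "exp",
    "tensor_sum",
    "tensor_mean",
    "concat",
    "maxpool2x2",
    "unfold",
    "softmax",
]


class Tensor:
    """A numpy array with an optional gradient and graph linkage.

    Parameters
    ----------
    data : array_like
        Wrapped values; always stored as float64.
    requires_grad : bool
        Whether backward() should accumulate a gradient into this node.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward_fn: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward_fn = _backward_fn

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this node.

        ``grad`` defaults to ones (natural for scalar losses).
        """
        if grad is None:
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward_fn is None or node.grad is None:
                continue
            grads = node._backward_fn(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                if not (parent.requires_grad or parent._parents):
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, _as_tensor(other))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(x) -> Tensor:
    """Wrap ``x`` as a constant (non-trainable) tensor."""
    return _as_tensor(x)


def parameter(x) -> Tensor:
    """Wrap ``x`` as a trainable tensor."""
    return Tensor(x, requires_grad=True)


def _track(*parents: Tensor) -> bool:
    return any(p.requires_grad or p._parents for p in parents)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data
    if not _track(a, b):
        return Tensor(out_data)

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return Tensor(out_data, _parents=(a, b), _backward_fn=backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data
    if not _track(a, b):
        return Tensor(out_data)

    def backward(g):
        return (_unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, _parents=(a, b), _backward_fn=backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data
    if not _track(a, b):
        return Tensor(out_data)

    def backward(g):
        ga = _unbroadcast(g / b.data, a.shape)
        gb = _unbroadcast(-g * a.data / (b.data ** 2), b.shape)
        return ga, gb

    return Tensor(out_data, _parents=(a, b), _backward_fn=backward)


def power(a: Tensor, p: float) -> Tensor:
    a = _as_tensor(a)
    p = float(p)
    out_data = a.data ** p
    if not _track(a):
        return Tensor(out_data)

    def backward(g):
        return (g * p * a.data ** (p - 1.0),)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Matrix product with numpy's batched-matmul broadcasting rules."""
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.matmul(a.data, b.data)
    if not _track(a, b):
        return Tensor(out_data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return Tensor(out_data, _parents=(a, b), _backward_fn=backward)


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def reshape(a: Tensor, shape: tuple) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)
    if not _track(a):
        return Tensor(out_data)

    def backward(g):
        return (g.reshape(a.shape),)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)


def transpose(a: Tensor, axes: tuple) -> Tensor:
    a = _as_tensor(a)
    out_data = np.transpose(a.data, axes)
    if not _track(a):
        return Tensor(out_data)
    inverse = np.argsort(axes)

    def backward(g):
        return (np.transpose(g, inverse),)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not _track(*tensors):
        return Tensor(out_data)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out_data, _parents=tuple(tensors), _backward_fn=backward)


# ---------------------------------------------------------------------------
# nonlinearities and reductions
# ---------------------------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.maximum(a.data, 0.0)
    if not _track(a):
        return Tensor(out_data)
    mask = a.data > 0.0

    def backward(g):
        return (g * mask,)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)


def sigmoid(a: Tensor) -> Tensor:
    from scipy.special import expit  # overflow-free logistic

    a = _as_tensor(a)
    out_data = expit(a.data)
    if not _track(a):
        return Tensor(out_data)

    def backward(g):
        return (g * out_data * (1.0 - out_data),)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)


def exp(a: Tensor) -> Tensor:
    a = _as_tensor(a)
    out_data = np.exp(a.data)
    if not _track(a):
        return Tensor(out_data)

    def backward(g):
        return (g * out_data,)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)


def tensor_sum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    if not _track(a):
        return Tensor(out_data)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)


def tensor_mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def softmax(a: Tensor, axis: int) -> Tensor:
    """Numerically stabilised softmax built from primitive ops.

    The max subtraction uses the forward values as a constant shift, which
    leaves both the value and the gradient of the softmax unchanged.
    """
    a = _as_tensor(a)
    shift = Tensor(np.max(a.data, axis=axis, keepdims=True))
    e = exp(a - shift)
    return div(e, tensor_sum(e, axis=axis, keepdims=True))


# ---------------------------------------------------------------------------
# spatial primitives
# ---------------------------------------------------------------------------

def maxpool2x2(a: Tensor) -> Tensor:
    """2x2 max pooling with stride 2 over the trailing two axes of (N,C,H,W)."""
    a = _as_tensor(a)
    n, c, h, w = a.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 requires even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    windows = a.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    windows = windows.reshape(n, c, h2, w2, 4)
    arg = np.argmax(windows, axis=-1)
    out_data = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
    if not _track(a):
        return Tensor(out_data)

    def backward(g):
        gw = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(gw, arg[..., None], g[..., None], axis=-1)
        gw = gw.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gw.reshape(n, c, h, w),)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)


def unfold(a: Tensor, ksize: int, padding: int, pad_mode: str = "zeros") -> Tensor:
    """Extract all stride-1 ``ksize`` x ``ksize`` patches.

    Input (N, C, H, W) -> output (N, C, ksize*ksize, H*W); with
    ``padding == (ksize - 1) // 2`` the spatial extent is preserved.
    ``pad_mode`` is ``"zeros"`` or ``"reflect"``.
    """
    a = _as_tensor(a)
    if ksize % 2 == 0:
        raise ValueError(f"unfold window must be odd, got {ksize}")
    if pad_mode not in ("zeros", "reflect"):
        raise ValueError(f"unknown pad_mode {pad_mode!r}")
    n, c, h, w = a.shape
    p = padding
    if pad_mode == "zeros":
        padded = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p)))
    else:
        padded = np.pad(a.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")
    hp, wp = h + 2 * p, w + 2 * p
    ho, wo = hp - ksize + 1, wp - ksize + 1
    out_data = np.empty((n, c, ksize * ksize, ho * wo))
    out_view = out_data.reshape(n, c, ksize * ksize, ho, wo)
    for ki in range(ksize):
        for kj in range(ksize):
            np.copyto(out_view[:, :, ki * ksize + kj],
                      padded[:, :, ki:ki + ho, kj:kj + wo])
    if not _track(a):
        return Tensor(out_data)

    def backward(g):
        g = g.reshape(n, c, ksize, ksize, ho, wo)
        gpad = np.zeros((n, c, hp, wp))
        for ki in range(ksize):
            for kj in range(ksize):
                gpad[:, :, ki:ki + ho, kj:kj + wo] += g[:, :, ki, kj]
        if pad_mode == "zeros" or p == 0:
            return (gpad[:, :, p:hp - p, p:wp - p].copy(),)
        # fold reflected border contributions back onto their source pixels
        idx = np.pad(np.arange(h * w).reshape(h, w), p, mode="reflect").ravel()
        flat = gpad.reshape(n * c, hp * wp)
        out = np.empty((n * c, h * w))
        for i in range(n * c):
            out[i] = np.bincount(idx, weights=flat[i], minlength=h * w)
        return (out.reshape(n, c, h, w),)

    return Tensor(out_data, _parents=(a,), _backward_fn=backward)
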