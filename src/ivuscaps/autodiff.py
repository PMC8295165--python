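"""Minimal reverse-mode automatic differentiation on numpy arrays.

The capsule layers in this package need gradients through an *unrolled*
iterative routing procedure, so every primitive here is differentiable and
the whole forward graph (including all routing iterations) is retained for
the backward pass.  The engine is deliberately small: dense numpy arrays,
define-by-run taping, no broadcasting surprises beyond numpy's own rules.

Only the primitives the networks actually use are implemented.  2-D
"spatial" primitives (:func:`unfold2d`, :func:`dilate2d`, :func:`repeat2d`,
:func:`pad2d`) operate on the two *leading* axes, matching the
``[height, width, channels...]`` layout used throughout the package.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "astensor",
    "add", "mul", "matmul", "einsum", "concatenate",
    "exp", "log", "sqrt", "absolute", "square", "relu", "maximum",
    "tsum", "tmean", "amax", "softmax", "narrow",
    "reshape", "transpose", "pad2d", "unfold2d", "dilate2d", "repeat2d",
    "shiftsum2d",
    "no_grad", "is_grad_enabled",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- array-ish surface ------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, _reciprocal(other))

    def __rtruediv__(self, other):
        return mul(_reciprocal(self), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        if p == 2:
            return square(self)
        return _power(self, p)

    def __getitem__(self, idx):
        return _getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def max(self, axis=None, keepdims=False):
        return amax(self, axis=axis, keepdims=keepdims)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- backward ---------------------------------------------------------
    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        if grad is None:
            if self.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)

        order = _toposort(self)
        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in order:
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                parent_grads = node._backward(g)
                for parent, pg in zip(node._parents, parent_grads):
                    if pg is None or not parent.requires_grad:
                        continue
                    acc = grads.get(id(parent))
                    grads[id(parent)] = pg if acc is None else acc + pg
            elif node.requires_grad:
                # leaf: accumulate into .grad
                node.grad = g if node.grad is None else node.grad + g


class Parameter(Tensor):
    """A leaf tensor holding learnable weights."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


def _toposort(root: Tensor) -> list[Tensor]:
    seen: set[int] = set()
    order: list[Tensor] = []
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    order.reverse()
    return order


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _coerce_pair(a, b):
    """Wrap operands, keeping python scalars in the other operand's dtype
    (a bare float must not silently promote a float32 graph to float64)."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor) and np.isscalar(b):
        return a, Tensor(np.asarray(b, dtype=a.data.dtype))
    if isinstance(b, Tensor) and not isinstance(a, Tensor) and np.isscalar(a):
        return Tensor(np.asarray(a, dtype=b.data.dtype)), b
    return astensor(a), astensor(b)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- elementwise ----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _coerce_pair(a, b)

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(a.data + b.data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _coerce_pair(a, b)

    def backward(g):
        return (_unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def _reciprocal(a) -> Tensor:
    a = astensor(a)
    out_data = 1.0 / a.data

    def backward(g):
        return (-g * out_data * out_data,)

    return _make(out_data, (a,), backward)


def _power(a, p: float) -> Tensor:
    a = astensor(a)

    def backward(g):
        return (g * p * np.power(a.data, p - 1),)

    return _make(np.power(a.data, p), (a,), backward)


def square(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        return (2.0 * g * a.data,)

    return _make(a.data * a.data, (a,), backward)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        return (g * out_data,)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        return (g / a.data,)

    return _make(np.log(a.data), (a,), backward)


def sqrt(a) -> Tensor:
    a = astensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        return (g * (0.5 / out_data),)

    return _make(out_data, (a,), backward)


def absolute(a) -> Tensor:
    a = astensor(a)

    def backward(g):
        return (g * np.sign(a.data),)

    return _make(np.abs(a.data), (a,), backward)


def relu(a) -> Tensor:
    a = astensor(a)
    mask = a.data > 0

    def backward(g):
        return (g * mask,)

    return _make(np.where(mask, a.data, 0.0), (a,), backward)


def maximum(a, b) -> Tensor:
    """Elementwise maximum; ties route the gradient to the first argument."""
    a, b = _coerce_pair(a, b)
    take_a = a.data >= b.data

    def backward(g):
        return (_unbroadcast(np.where(take_a, g, 0.0), a.shape),
                _unbroadcast(np.where(take_a, 0.0, g), b.shape))

    return _make(np.where(take_a, a.data, b.data), (a, b), backward)


# -- reductions -----------------------------------------------------------

def _norm_axis(axis, ndim):
    if axis is None:
        return None
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    axis = _norm_axis(axis, a.ndim)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    axis = _norm_axis(axis, a.ndim)
    if axis is None:
        n = a.size
    else:
        n = int(np.prod([a.shape[i] for i in axis]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def amax(a, axis=None, keepdims=False) -> Tensor:
    """Maximum reduction; gradient is split evenly among tied maxima."""
    a = astensor(a)
    axis = _norm_axis(axis, a.ndim)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data).astype(a.data.dtype)
    mask /= mask.sum(axis=axis, keepdims=True)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        elif axis is None:
            g = np.reshape(g, (1,) * a.ndim)
        return (mask * g,)

    res = out_data if keepdims or axis is None else np.squeeze(out_data, axis=axis)
    if axis is None and not keepdims:
        res = res.reshape(())
    return _make(res, (a,), backward)


def softmax(a, axis=-1) -> Tensor:
    a = astensor(a)
    if axis in (-1, a.ndim - 1):
        from ._fused import softmax_lastaxis_backward, softmax_lastaxis_forward

        out_data = softmax_lastaxis_forward(
            np.ascontiguousarray(a.data.reshape(-1, a.shape[-1])))
        out_data = out_data.reshape(a.shape)

        def backward(g):
            flat = softmax_lastaxis_backward(
                np.ascontiguousarray(out_data.reshape(-1, a.shape[-1])),
                np.ascontiguousarray(g.reshape(-1, a.shape[-1])))
            return (flat.reshape(a.shape),)

        return _make(out_data, (a,), backward)

    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        return (out_data * (g - dot),)

    return _make(out_data, (a,), backward)


# -- linear algebra -------------------------------------------------------

def matmul(a, b) -> Tensor:
    """Batched matrix product with numpy broadcasting over leading axes."""
    a, b = astensor(a), astensor(b)

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _make(a.data @ b.data, (a, b), backward)


def einsum(subscripts: str, *tensors) -> Tensor:
    """Differentiable einsum.

    Restriction: every index of every operand must also appear in the output
    or in another operand (no single-operand traces/diagonals), which holds
    for all contractions used in this package.
    """
    tensors = [astensor(t) for t in tensors]
    in_spec, out_spec = subscripts.replace(" ", "").split("->")
    in_specs = in_spec.split(",")
    if len(in_specs) != len(tensors):
        raise ValueError("einsum operand count mismatch")

    def backward(g):
        grads = []
        for k, spec_k in enumerate(in_specs):
            others = [(s, t.data) for i, (s, t) in enumerate(zip(in_specs, tensors)) if i != k]
            lhs = ",".join([out_spec] + [s for s, _ in others])
            sub = f"{lhs}->{spec_k}"
            operands = [g] + [d for _, d in others]
            grads.append(np.einsum(sub, *operands))
        return tuple(grads)

    return _make(np.einsum(subscripts, *[t.data for t in tensors]), tensors, backward)


# -- shape manipulation ---------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = astensor(a)

    def backward(g):
        return (g.reshape(a.shape),)

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        return (g.transpose(inv),)

    return _make(a.data.transpose(axes), (a,), backward)


def _getitem(a, idx) -> Tensor:
    a = astensor(a)

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return (out,)

    return _make(a.data[idx], (a,), backward)


def narrow(a, start: int, stop: int, axis: int = -1) -> Tensor:
    """Contiguous slice along one axis (cheap backward via zero-fill)."""
    a = astensor(a)
    axis = axis % a.ndim
    idx = tuple([slice(None)] * axis + [slice(start, stop)])

    def backward(g):
        out = np.zeros_like(a.data)
        out[idx] = g
        return (out,)

    return _make(a.data[idx], (a,), backward)


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tensors, backward)


def pad2d(a, pad: int) -> Tensor:
    """Zero-pad the two leading (spatial) axes by `pad` on each side."""
    a = astensor(a)
    if pad == 0:
        return a
    h, w = a.shape[:2]
    out_data = np.zeros((h + 2 * pad, w + 2 * pad) + a.shape[2:], dtype=a.data.dtype)
    out_data[pad:-pad, pad:-pad] = a.data

    def backward(g):
        return (g[pad:-pad, pad:-pad],)

    return _make(out_data, (a,), backward)


def unfold2d(a, window: int, stride: int = 1) -> Tensor:
    """Extract sliding windows over the two leading axes.

    Input ``[H, W, rest...]`` (already padded) maps to
    ``[Ho, Wo, window, window, rest...]`` with
    ``Ho = (H - window) // stride + 1``.
    """
    a = astensor(a)
    H, W = a.shape[:2]
    k = window
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    rest = a.shape[2:]
    if stride == 1:
        sw = np.lib.stride_tricks.sliding_window_view(a.data, (k, k), axis=(0, 1))
        perm = (0, 1, 2 + len(rest), 3 + len(rest)) + tuple(range(2, 2 + len(rest)))
        out_data = np.ascontiguousarray(sw.transpose(perm))
    else:
        out_data = np.empty((Ho, Wo, k, k) + rest, dtype=a.data.dtype)
        for di in range(k):
            for dj in range(k):
                out_data[:, :, di, dj] = a.data[di:di + stride * Ho:stride,
                                                dj:dj + stride * Wo:stride]

    def backward(g):
        ga = np.zeros_like(a.data)
        for di in range(k):
            for dj in range(k):
                ga[di:di + stride * Ho:stride,
                   dj:dj + stride * Wo:stride] += g[:, :, di, dj]
        return (ga,)

    return _make(out_data, (a,), backward)


def shiftsum2d(a, window: int, stride: int = 1) -> Tensor:
    """Sum of each sliding window over the two leading axes.

    Equivalent to ``unfold2d(a, k, stride).sum(axis=(2, 3))`` but computed
    by accumulating the k*k shifted slices directly, without materializing
    the windowed tensor.  Used for routing iterations whose coefficients
    are uniform.
    """
    a = astensor(a)
    H, W = a.shape[:2]
    k = window
    Ho = (H - k) // stride + 1
    Wo = (W - k) // stride + 1
    out_data = np.zeros((Ho, Wo) + a.shape[2:], dtype=a.data.dtype)
    for di in range(k):
        for dj in range(k):
            out_data += a.data[di:di + stride * Ho:stride,
                               dj:dj + stride * Wo:stride]

    def backward(g):
        ga = np.zeros_like(a.data)
        for di in range(k):
            for dj in range(k):
                ga[di:di + stride * Ho:stride,
                   dj:dj + stride * Wo:stride] += g
        return (ga,)

    return _make(out_data, (a,), backward)


def dilate2d(a, factor: int) -> Tensor:
    """Insert ``factor - 1`` zero rows/cols after each spatial element.

    ``[H, W, rest]`` maps to ``[H * factor, W * factor, rest]`` with the
    input located at strided positions — the standard input dilation used to
    express a transposed (fractionally strided) convolution as an ordinary
    one.
    """
    a = astensor(a)
    if factor == 1:
        return a
    H, W = a.shape[:2]
    out_shape = (H * factor, W * factor) + a.shape[2:]
    out_data = np.zeros(out_shape, dtype=a.data.dtype)
    out_data[::factor, ::factor] = a.data

    def backward(g):
        return (g[::factor, ::factor].copy(),)

    return _make(out_data, (a,), backward)


def repeat2d(a, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of the two leading axes."""
    a = astensor(a)
    if factor == 1:
        return a
    H, W = a.shape[:2]
    rest = a.shape[2:]

    def backward(g):
        g = g.reshape((H, factor, W, factor) + rest)
        return (g.sum(axis=(1, 3)),)

    out = np.repeat(np.repeat(a.data, factor, axis=0), factor, axis=1)
    return _make(out, (a,), backward)
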