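"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine: a :class:`Tensor` wraps an
``ndarray`` and remembers the operation that produced it, so a single
call to :meth:`Tensor.backward` accumulates gradients through arbitrary
compositions of the primitives defined here.  Only the operations the
package's models need are provided (dense algebra, convolutions, pooling,
pointwise nonlinearities, a two-operand ``einsum``, softmax and a fused
softmax cross-entropy).  Everything is float64 for the benefit of the
oracle-equivalence tests.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: Tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[Array] = None
        self.requires_grad = bool(requires_grad)
        self._parents: Tuple["Tensor", ...] = ()
        self._backward_fn: Optional[Callable[[Array], Sequence[Optional[Array]]]] = None

    # -- construction helper ------------------------------------------------
    @staticmethod
    def _result(data: Array, parents: Tuple["Tensor", ...],
                backward_fn: Callable[[Array], Sequence[Optional[Array]]]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward_fn = backward_fn
        return out

    # -- basic protocol -----------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> Array:
        return self.data

    # -- autodiff -----------------------------------------------------------
    def backward(self, grad: Optional[Array] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        # topological order (iterative to cope with long LSTM chains)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        grads: dict[int, Array] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward_fn is None:
                continue
            parent_grads = node._backward_fn(g)
            for parent, pg in zip(node._parents, parent_grads):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators ----------------------------------------------------------
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
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)

    # -- convenience reductions --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        return tensor_sum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        return tensor_mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return Tensor._result(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** p

    def backward(g):
        return (g * p * a.data ** (p - 1.0),)

    return Tensor._result(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return Tensor._result(data, (a, b), backward)


def einsum(spec: str, a, b) -> Tensor:
    """Two-operand einsum.

    Restricted to specs where every index of each operand also appears in
    the output or in the other operand (true for all contractions used by
    the capsule layers), which makes each operand's gradient another
    einsum with permuted subscripts.
    """
    a, b = _as_tensor(a), _as_tensor(b)
    ins, out = spec.split("->")
    sa, sb = ins.split(",")
    if not (set(sa) <= set(out) | set(sb) and set(sb) <= set(out) | set(sa)):
        raise ValueError(f"unsupported einsum spec for autodiff: {spec}")
    data = np.einsum(spec, a.data, b.data)

    def backward(g):
        ga = np.einsum(f"{out},{sb}->{sa}", g, b.data)
        gb = np.einsum(f"{sa},{out}->{sb}", a.data, g)
        return ga, gb

    return Tensor._result(data, (a, b), backward)


def tensor_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return Tensor._result(data, (a,), backward)


def tensor_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        denom = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        denom = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / denom)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.data.shape),)

    return Tensor._result(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        return (g.transpose(inv),)

    return Tensor._result(data, (a,), backward)


def getitem(a, key) -> Tensor:
    a = _as_tensor(a)
    data = a.data[key]

    def backward(g):
        out = np.zeros_like(a.data)
        np.add.at(out, key, g)
        return (out,)

    return Tensor._result(data, (a,), backward)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        grads = []
        for i in range(len(tensors)):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            grads.append(g[tuple(sl)])
        return grads

    return Tensor._result(data, tuple(tensors), backward)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = _as_tensor(t)
        shape = list(t.data.shape)
        shape.insert(axis, 1)
        expanded.append(reshape(t, tuple(shape)))
    return concatenate(expanded, axis=axis)


# -- pointwise nonlinearities ------------------------------------------------

def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        return (g * data * (1.0 - data),)

    return Tensor._result(data, (a,), backward)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        return (g * (1.0 - data * data),)

    return Tensor._result(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        return (g * (a.data > 0.0),)

    return Tensor._result(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        return (g * data,)

    return Tensor._result(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        return (g / a.data,)

    return Tensor._result(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        return (g * 0.5 / data,)

    return Tensor._result(data, (a,), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return a
    keep = 1.0 - rate
    mask = (rng.random(a.data.shape) < keep) / keep
    return mul(a, Tensor(mask))


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        return (data * (g - dot),)

    return Tensor._result(data, (a,), backward)


def softmax_cross_entropy(logits: Tensor, onehot: Array) -> Tensor:
    """Mean categorical cross-entropy of ``logits`` against one-hot targets."""
    logits = _as_tensor(logits)
    y = np.asarray(onehot, dtype=np.float64)
    if y.shape != logits.data.shape:
        raise ValueError("targets must match logits shape")
    shifted = logits.data - logits.data.max(axis=-1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    logp = shifted - logz
    n = logits.data.shape[0]
    data = -(y * logp).sum() / n
    probs = np.exp(logp)

    def backward(g):
        return (g * (probs - y) / n,)

    return Tensor._result(np.asarray(data), (logits,), backward)


# -- convolutions & pooling --------------------------------------------------

def _same_pad_1d(length: int, kernel: int, stride: int) -> Tuple[int, int]:
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    return total // 2, total - total // 2


def conv1d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1,
           padding: str = "same") -> Tensor:
    """1D convolution. ``x``: (N, T, C); ``w``: (k, C, F); ``b``: (F,)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    n, t, c = x.data.shape
    k, c2, f = w.data.shape
    if c != c2:
        raise ValueError(f"input has {c} channels, kernel expects {c2}")
    if padding == "same":
        left, right = _same_pad_1d(t, k, stride)
    elif padding == "valid":
        left = right = 0
        if k > t:
            raise ValueError("kernel larger than input under valid padding")
    else:
        raise ValueError(f"unknown padding {padding!r}")
    xp = np.pad(x.data, ((0, 0), (left, right), (0, 0)))
    tp = xp.shape[1]
    out_len = (tp - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
    windows = windows[:, ::stride]              # (N, out, C, k)
    cols = windows.transpose(0, 1, 3, 2).reshape(n, out_len, k * c)
    wm = w.data.reshape(k * c, f)
    data = cols @ wm + b.data

    def backward(g):
        gcols = g @ wm.T                        # (N, out, k*C)
        gw = np.einsum("nok,nof->kf", cols, g).reshape(k, c, f)
        gb = g.sum(axis=(0, 1))
        gxp = np.zeros_like(xp)
        gc = gcols.reshape(n, out_len, k, c)
        starts = np.arange(out_len) * stride
        for ki in range(k):
            gxp[:, starts + ki, :] += gc[:, :, ki, :]
        gx = gxp[:, left:left + t, :]
        return gx, gw, gb

    return Tensor._result(data, (x, w, b), backward)


def conv2d_valid(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2D valid convolution, stride 1. ``x``: (N, H, W, C); ``w``: (kh, kw, C, F)."""
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    n, h, wd, c = x.data.shape
    kh, kw, c2, f = w.data.shape
    if c != c2:
        raise ValueError(f"input has {c} channels, kernel expects {c2}")
    if kh > h or kw > wd:
        raise ValueError("kernel larger than input under valid padding")
    oh, ow = h - kh + 1, wd - kw + 1
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(1, 2))
    # windows: (N, oh, ow, C, kh, kw) -> (N, oh*ow, kh*kw*C)
    cols = windows.transpose(0, 1, 2, 4, 5, 3).reshape(n, oh * ow, kh * kw * c)
    wm = w.data.reshape(kh * kw * c, f)
    data = (cols @ wm + b.data).reshape(n, oh, ow, f)

    def backward(g):
        gf = g.reshape(n, oh * ow, f)
        gcols = gf @ wm.T
        gw = np.einsum("nok,nof->kf", cols, gf).reshape(kh, kw, c, f)
        gb = gf.sum(axis=(0, 1))
        gx = np.zeros_like(x.data)
        gc = gcols.reshape(n, oh, ow, kh, kw, c)
        for ki in range(kh):
            for kj in range(kw):
                gx[:, ki:ki + oh, kj:kj + ow, :] += gc[:, :, :, ki, kj, :]
        return gx, gw, gb

    return Tensor._result(data, (x, w, b), backward)


def avg_pool2d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping average pooling; trailing rows/cols are dropped (floor)."""
    x = _as_tensor(x)
    n, h, w, c = x.data.shape
    oh, ow = h // pool, w // pool
    cropped = x.data[:, :oh * pool, :ow * pool, :]
    blocks = cropped.reshape(n, oh, pool, ow, pool, c)
    data = blocks.mean(axis=(2, 4))

    def backward(g):
        gx = np.zeros_like(x.data)
        gb = np.repeat(np.repeat(g, pool, axis=1), pool, axis=2) / (pool * pool)
        gx[:, :oh * pool, :ow * pool, :] = gb
        return (gx,)

    return Tensor._result(data, (x,), backward)


def l2_norm(a: Tensor, axis: int = -1, keepdims: bool = False,
            eps: float = 1e-12) -> Tensor:
    """Smoothed Euclidean norm sqrt(sum a^2 + eps); differentiable at 0."""
    return sqrt(tensor_sum(mul(a, a), axis=axis, keepdims=keepdims) + eps)
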