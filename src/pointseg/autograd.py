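"""A compact reverse-mode automatic-differentiation engine on numpy.

Provides exactly the operator set the multi-decoder segmentation network
and its losses need: broadcast arithmetic, matmul, conv2d (im2col),
pooling, nearest upsampling, reflect padding, reshapes, softmax building
blocks, and an Adam optimizer. Gradients are accumulated on ``Tensor``
leaves by :meth:`Tensor.backward` over a topologically sorted tape.

All data is float64; correctness of every backward rule is pinned by
finite-difference tests.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
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

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, n in enumerate(shape):
        if n == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------- arithmetic
def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(go):
        a._accumulate(_unbroadcast(go, a.shape))
        b._accumulate(_unbroadcast(go, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(go):
        a._accumulate(_unbroadcast(go * b.data, a.shape))
        b._accumulate(_unbroadcast(go * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(go):
        a._accumulate(_unbroadcast(go / b.data, a.shape))
        b._accumulate(_unbroadcast(-go * a.data / (b.data ** 2), b.shape))

    return _make(out_data, (a, b), backward)


def power(a, exponent: float):
    a = as_tensor(a)
    out_data = a.data ** exponent

    def backward(go):
        a._accumulate(go * exponent * a.data ** (exponent - 1))

    return _make(out_data, (a,), backward)


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(go):
        a._accumulate(go * out_data)

    return _make(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(go):
        a._accumulate(go / a.data)

    return _make(out_data, (a,), backward)


def clip(a, lo: float, hi: float):
    """Clamp values; gradient flows only through the un-clamped region."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    passthrough = (a.data > lo) & (a.data < hi)

    def backward(go):
        a._accumulate(go * passthrough)

    return _make(out_data, (a,), backward)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def backward(go):
        a._accumulate(go * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(go):
        a._accumulate(go * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(go):
        ga = go @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ go
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _make(out_data, (a, b), backward)


# ------------------------------------------------------------------ reshapes
def reshape(a, shape):
    a = as_tensor(a)
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    old = a.shape

    def backward(go):
        a._accumulate(go.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes):
    a = as_tensor(a)
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    inv = np.argsort(axes)

    def backward(go):
        a._accumulate(go.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis: int = 0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(go):
        for t, g in zip(tensors, np.split(go, splits, axis=axis)):
            t._accumulate(g)

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(go):
        g = go
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def softmax(a, axis: int = -1):
    """Numerically stable softmax (max-shift treated as a constant)."""
    a = as_tensor(a)
    shifted = add(a, Tensor(-a.data.max(axis=axis, keepdims=True)))
    e = exp(shifted)
    return div(e, tsum(e, axis=axis, keepdims=True))


def take(a, index: int, axis: int):
    """Select one index along ``axis`` (the axis is removed)."""
    a = as_tensor(a)
    sel = [slice(None)] * a.ndim
    sel[axis] = index
    sel = tuple(sel)

    def backward(go):
        g = np.zeros_like(a.data)
        g[sel] = go
        a._accumulate(g)

    return _make(a.data[sel], (a,), backward)


# --------------------------------------------------------------- image ops
def conv2d(x, w, b=None, stride: int = 1, padding: int = 0):
    """2-D convolution (cross-correlation): x (N,C,H,W), w (O,C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    view = view[:, :, ::s, ::s]  # (N, C, Ho, Wo, kh, kw)
    ho, wo = view.shape[2], view.shape[3]
    out_data = np.einsum("nchwij,ocij->nohw", view, w.data, optimize=True)
    parents = [x, w]
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents.append(b)

    def backward(go):
        gw = np.einsum("nchwij,nohw->ocij", view, go, optimize=True)
        w._accumulate(gw)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += np.einsum(
                    "nohw,oc->nchw", go, w.data[:, :, i, j], optimize=True
                )
        if padding:
            gxp = gxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(gxp)
        if b is not None:
            b._accumulate(go.sum(axis=(0, 2, 3)))

    return _make(out_data, parents, backward)


def avg_pool2d(x, k: int = 2):
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"pooling window {k} must divide spatial dims {(h, w)}")
    out_data = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def backward(go):
        g = np.repeat(np.repeat(go, k, axis=2), k, axis=3) / (k * k)
        x._accumulate(g)

    return _make(out_data, (x,), backward)


def upsample_nearest(x, scale=2):
    x = as_tensor(x)
    sh, sw = (scale, scale) if isinstance(scale, int) else scale
    out_data = np.repeat(np.repeat(x.data, sh, axis=2), sw, axis=3)

    def backward(go):
        n, c, h, w = x.shape
        g = go.reshape(n, c, h, sh, w, sw).sum(axis=(3, 5))
        x._accumulate(g)

    return _make(out_data, (x,), backward)


def _reflect_indices(n: int, before: int, after: int) -> np.ndarray:
    if n == 1:
        return np.zeros(before + n + after, dtype=np.int64)
    idx = np.arange(-before, n + after)
    idx = np.abs(idx)
    idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)
    if (idx < 0).any() or (idx >= n).any():
        raise ValueError("reflect padding wider than the input is not supported")
    return idx


def pad2d_reflect(x, pad_h: tuple[int, int], pad_w: tuple[int, int]):
    """Reflect-pad the last two axes of a (N,C,H,W) tensor."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    ridx = _reflect_indices(h, *pad_h)
    cidx = _reflect_indices(w, *pad_w)
    out_data = x.data[:, :, ridx[:, None], cidx[None, :]]

    def backward(go):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (slice(None), slice(None), ridx[:, None], cidx[None, :]), go)
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


def crop2d(x, h: int, w: int):
    """Keep the top-left h x w window of the last two axes."""
    x = as_tensor(x)
    out_data = x.data[:, :, :h, :w]

    def backward(go):
        gx = np.zeros_like(x.data)
        gx[:, :, :h, :w] = go
        x._accumulate(gx)

    return _make(out_data, (x,), backward)


# ------------------------------------------------------------------- modules
class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Tensor]:
        params = []
        for value in self.__dict__.values():
            params.extend(_collect(value))
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model expects {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.shape}")
            p.data = arr.copy()


def _collect(value):
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x):
        return matmul(x, self.weight) + self.bias


class Conv2d(Module):
    def __init__(self, c_in, c_out, k, rng, stride=1, padding=None, bias=True):
        if padding is None:
            padding = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.weight = Tensor(
            rng.normal(0, scale, size=(c_out, c_in, k, k)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    """Group normalisation over (N, C, H, W); batch-size independent, so
    train and eval behave identically (no running statistics to manage)."""

    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5):
        self.groups = groups if groups is not None else min(8, channels)
        if channels % self.groups:
            self.groups = 1
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias = Tensor(np.zeros(channels), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        n, c, h, w = x.shape
        g = self.groups
        xg = reshape(x, (n, g, (c // g) * h * w))
        mu = tmean(xg, axis=2, keepdims=True)
        centered = xg - mu
        var = tmean(power(centered, 2.0), axis=2, keepdims=True)
        norm = div(centered, power(var + self.eps, 0.5))
        out = reshape(norm, (n, c, h, w))
        return out * reshape(self.weight, (1, c, 1, 1)) + reshape(self.bias, (1, c, 1, 1))


class LayerNorm(Module):
    """Layer normalisation over the last axis (token channels)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        mu = tmean(x, axis=-1, keepdims=True)
        centered = x - mu
        var = tmean(power(centered, 2.0), axis=-1, keepdims=True)
        return div(centered, power(var + self.eps, 0.5)) * self.weight + self.bias


class Adam:
    """Adam with decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.asarray(a) for a in state["m"]]
        self.v = [np.asarray(a) for a in state["v"]]
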