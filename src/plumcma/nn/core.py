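"""Minimal reverse-mode autodiff over numpy arrays.

Covers exactly the operator set needed by the detector blocks: grouped 2-D
convolution (im2col), batch normalization, SiLU/sigmoid/softmax, batched
matmul, concatenation/slicing, nearest upsampling, and elementwise
arithmetic. Float32 throughout; gradients accumulate on leaves with
``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- plumbing -----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))
        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))
        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))
        return self._make(self.data / other.data, (self, other), bw)

    def __matmul__(self, other):
        other = self._coerce(other)

        def bw(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))
        return self._make(self.data @ other.data, (self, other), bw)

    def pow(self, exponent: float):
        def bw(g):
            self._accum(g * exponent * self.data ** (exponent - 1))
        return self._make(self.data ** exponent, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)
        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self.pow(0.5)

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(np.ascontiguousarray(g.transpose(inv)))
        return self._make(np.ascontiguousarray(self.data.transpose(axes)), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return self._make(self.data[idx], (self,), bw)

    # -- activations --------------------------------------------------------

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 - s))
        return self._make(s, (self,), bw)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self._accum(g * s * (1.0 + self.data * (1.0 - s)))
        return self._make(self.data * s, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)
        return self._make(self.data * mask, (self,), bw)

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            inner = (g * p).sum(axis=axis, keepdims=True)
            self._accum(p * (g - inner))
        return self._make(p, (self,), bw)

    def maximum(self, other):
        other = self._coerce(other)
        mask = self.data >= other.data

        def bw(g):
            self._accum(_unbroadcast(g * mask, self.shape))
            other._accum(_unbroadcast(g * ~mask, other.shape))
        return self._make(np.maximum(self.data, other.data), (self, other), bw)

    def minimum(self, other):
        other = self._coerce(other)
        mask = self.data <= other.data

        def bw(g):
            self._accum(_unbroadcast(g * mask, self.shape))
            other._accum(_unbroadcast(g * ~mask, other.shape))
        return self._make(np.minimum(self.data, other.data), (self, other), bw)

    def clamp_min(self, v: float):
        return self.maximum(Tensor(np.float32(v)))


# -- structural ops ---------------------------------------------------------

def cat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])
    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def chunk(t: Tensor, n: int, axis: int = 1) -> list[Tensor]:
    size = t.shape[axis] // n
    outs = []
    for i in range(n):
        sl = [slice(None)] * t.ndim
        sl[axis] = slice(i * size, (i + 1) * size)
        outs.append(t[tuple(sl)])
    return outs


def upsample_nearest2x(t: Tensor) -> Tensor:
    n, c, h, w = t.shape

    def bw(g):
        t._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    return Tensor._make(np.repeat(np.repeat(t.data, 2, axis=2), 2, axis=3), (t,), bw)


def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """Sliding k x k windows with stride from a padded NCHW array.

    Returns a strided view (N, C, Ho, Wo, k, k).
    """
    n, c, hp, wp = xp.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    sn, sc, sh, sw = xp.strides
    return np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, ho, wo, k, k),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    )


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution, NCHW, square kernel."""
    n, cin, h, w = x.shape
    cout, cin_g, k, _ = weight.shape
    assert cin_g * groups == cin, "channel/group mismatch"
    cog = cout // groups

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _windows(xp, k, stride)  # N, C, Ho, Wo, k, k
    ho, wo = win.shape[2], win.shape[3]
    wing = win.reshape(n, groups, cin_g, ho, wo, k, k)
    wg = weight.data.reshape(groups, cog, cin_g, k, k)
    out = np.einsum("ngchwkl,gdckl->ngdhw", wing, wg, optimize=True)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gg = g.reshape(n, groups, cog, ho, wo)
        gw = np.einsum("ngchwkl,ngdhw->gdckl", wing, gg, optimize=True)
        weight._accum(gw.reshape(cout, cin_g, k, k))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2, 3)))
        gxp = np.zeros_like(xp).reshape(n, groups, cin_g, *xp.shape[2:])
        for ki in range(k):
            for kj in range(k):
                # contribution of weight tap (ki, kj) to each input position
                contrib = np.einsum("gdc,ngdhw->ngchw", wg[:, :, :, ki, kj], gg, optimize=True)
                gxp[:, :, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += contrib
        gx = gxp.reshape(n, cin, *xp.shape[2:])
        if padding:
            gx = gx[:, :, padding:-padding, padding:-padding]
        x._accum(gx)

    return Tensor._make(out, parents, bw)


def batch_norm(x: Tensor, weight: Tensor, bias: Tensor, running_mean: np.ndarray,
               running_var: np.ndarray, training: bool, momentum: float = 0.03,
               eps: float = 1e-3) -> Tensor:
    """2-D batch normalization over (N, H, W) per channel."""
    n, c, h, w = x.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        m = n * h * w
        unbiased = var * (m / max(m - 1, 1))
        running_var *= (1 - momentum)
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var

    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out = xhat * weight.data.reshape(1, c, 1, 1) + bias.data.reshape(1, c, 1, 1)

    def bw(g):
        weight._accum((g * xhat).sum(axis=(0, 2, 3)))
        bias._accum(g.sum(axis=(0, 2, 3)))
        gw = g * weight.data.reshape(1, c, 1, 1)
        if training:
            m = n * h * w
            gsum = gw.sum(axis=(0, 2, 3), keepdims=True)
            gxsum = (gw * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (inv_std.reshape(1, c, 1, 1) / m) * (m * gw - gsum - xhat * gxsum)
        else:
            gx = gw * inv_std.reshape(1, c, 1, 1)
        x._accum(gx.astype(np.float32))

    return Tensor._make(out, (x, weight, bias), bw)
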