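"""Detector building blocks.

Includes the baseline lineage's blocks (bottlenecks, C3k/C3k2, area-attention
A2C2f, decoupled detect head) plus the two contributed modules:

* :class:`CIB` / :class:`C2fCIB` -- compact inverted bottleneck (1x1 expand ->
  3x3 depthwise -> 1x1 squeeze, SiLU after each stage) inside a split /
  shortcut / concat / fuse frame.
* :class:`GatedCNNBlock` / :class:`C3k2Mambaout` -- gated convolution block
  computing ``Y = (TokenMixer(X'W1) (*) silu(X'W2)) W3 + X`` with
  ``X' = Norm(X)``; the token mixer is a cascade of depthwise convolutions
  while the second path contributes multiplicative spatial gating.
"""

from __future__ import annotations

import numpy as np

from .core import Tensor, cat, chunk
from .layers import Conv, Conv2d, DWConv, Module, ModuleList, Parameter, Sequential


class Bottleneck(Module):
    def __init__(self, c1: int, c2: int, shortcut: bool = True, g: int = 1,
                 k: tuple[int, int] = (3, 3), e: float = 0.5):
        super().__init__()
        c_ = int(c2 * e)
        k1 = k[0] if isinstance(k[0], int) else k[0][0]
        k2 = k[1] if isinstance(k[1], int) else k[1][0]
        self.cv1 = Conv(c1, c_, k1, 1)
        self.cv2 = Conv(c_, c2, k2, 1, g=g)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C3(Module):
    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 g: int = 1, e: float = 0.5):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv(c1, c_, 1, 1)
        self.cv3 = Conv(2 * c_, c2, 1)
        self.m = ModuleList(
            Bottleneck(c_, c_, shortcut, g, k=((1, 1), (3, 3)), e=1.0) for _ in range(n)
        )

    def forward(self, x):
        y = self.cv1(x)
        for m in self.m:
            y = m(y)
        return self.cv3(cat([y, self.cv2(x)], 1))


class C3k(C3):
    """C3 with configurable bottleneck kernel (3 by default)."""

    def __init__(self, c1: int, c2: int, n: int = 1, shortcut: bool = True,
                 g: int = 1, e: float = 0.5, k: int = 3):
        super().__init__(c1, c2, n, shortcut, g, e)
        c_ = int(c2 * e)
        self.m = ModuleList(
            Bottleneck(c_, c_, shortcut, g, k=(k, k), e=1.0) for _ in range(n)
        )


class C3k2(Module):
    """Split -> (bottleneck | C3k) chain -> concat -> fuse."""

    def __init__(self, c1: int, c2: int, n: int = 1, c3k: bool = False,
                 e: float = 0.5, g: int = 1, shortcut: bool = True):
        super().__init__()
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1)
        self.m = ModuleList(
            C3k(self.c, self.c, 2, shortcut, g) if c3k
            else Bottleneck(self.c, self.c, shortcut, g)
            for _ in range(n)
        )

    def forward(self, x):
        y = chunk(self.cv1(x), 2, 1)
        for m in self.m:
            y.append(m(y[-1]))
        return self.cv2(cat(y, 1))


class AAttn(Module):
    """Area attention: windowed multi-head attention over flattened tokens."""

    def __init__(self, dim: int, num_heads: int, area: int = 1):
        super().__init__()
        self.area = area
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.qkv = Conv(dim, dim * 3, 1, act=False)
        self.proj = Conv(dim, dim, 1, act=False)
        self.pe = Conv(dim, dim, 5, 1, 2, g=dim, act=False)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        n = h * w
        hd, heads = self.head_dim, self.num_heads

        qkv = self.qkv(x).reshape(b, 3 * c, n).transpose(0, 2, 1)  # B, N, 3C
        ba, na = b, n
        if self.area > 1:
            qkv = qkv.reshape(b * self.area, n // self.area, 3 * c)
            ba, na = b * self.area, n // self.area
        qkv = qkv.reshape(ba, na, heads, 3 * hd).transpose(0, 2, 3, 1)  # B, heads, 3hd, N
        q = qkv[:, :, 0:hd, :]
        k = qkv[:, :, hd:2 * hd, :]
        v = qkv[:, :, 2 * hd:3 * hd, :]

        attn = (q.transpose(0, 1, 3, 2) @ k) * (hd ** -0.5)
        from .layers import FlopProfile
        prof = FlopProfile.active
        if prof is not None:  # two batched matmuls per head
            prof.add_matmul_macs(2 * ba * heads * na * na * hd)
        attn = attn.softmax(axis=-1)
        out = v @ attn.transpose(0, 1, 3, 2)  # B, heads, hd, N

        out = out.transpose(0, 3, 1, 2).reshape(ba, na, c)
        vsp = v.transpose(0, 3, 1, 2).reshape(ba, na, c)
        if self.area > 1:
            out = out.reshape(b, n, c)
            vsp = vsp.reshape(b, n, c)
        out = out.reshape(b, h, w, c).transpose(0, 3, 1, 2)
        vsp = vsp.reshape(b, h, w, c).transpose(0, 3, 1, 2)
        return self.proj(out + self.pe(vsp))


class ABlock(Module):
    def __init__(self, dim: int, num_heads: int, mlp_ratio: float = 2.0, area: int = 1):
        super().__init__()
        self.attn = AAttn(dim, num_heads, area)
        hidden = int(dim * mlp_ratio)
        self.mlp = Sequential(Conv(dim, hidden, 1), Conv(hidden, dim, 1, act=False))

    def forward(self, x):
        x = x + self.attn(x)
        return x + self.mlp(x)


class A2C2f(Module):
    """Serial attention (or C3k) stages with intermediate outputs concatenated."""

    def __init__(self, c1: int, c2: int, n: int = 1, a2: bool = True, area: int = 1,
                 mlp_ratio: float = 2.0, e: float = 0.5, g: int = 1, shortcut: bool = True):
        super().__init__()
        c_ = int(c2 * e)
        assert c_ % 32 == 0 or not a2, "attention width must be a multiple of 32"
        self.cv1 = Conv(c1, c_, 1, 1)
        self.cv2 = Conv((1 + n) * c_, c2, 1)
        self.m = ModuleList(
            Sequential(*(ABlock(c_, c_ // 32, mlp_ratio, area) for _ in range(2)))
            if a2 else C3k(c_, c_, 2, shortcut, g)
            for _ in range(n)
        )

    def forward(self, x):
        y = [self.cv1(x)]
        for m in self.m:
            y.append(m(y[-1]))
        return self.cv2(cat(y, 1))


# -- contributed modules ----------------------------------------------------

class CIB(Module):
    """Compact inverted bottleneck: 1x1 expand -> 3x3 depthwise -> 1x1 squeeze.

    Each stage is conv + BN + SiLU; a residual shortcut is kept when the
    channel count is preserved.
    """

    def __init__(self, c1: int, c2: int, e: float = 2.0, shortcut: bool = True):
        super().__init__()
        if c1 < 1 or c2 < 1 or e <= 0:
            raise ValueError("channels must be >= 1 and expansion > 0")
        ec = int(c1 * e)
        self.cv1 = Conv(c1, ec, 1)
        self.cv2 = Conv(ec, ec, 3, g=ec)
        self.cv3 = Conv(ec, c2, 1)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv3(self.cv2(self.cv1(x)))
        return x + y if self.add else y


class C2fCIB(Module):
    """Split/shortcut fusion frame with a chain of CIB units.

    The initial 1x1 conv splits into a shortcut half and a processing half;
    the processing half runs through ``n`` serial CIBs with every intermediate
    retained; all (2 + n) branches concatenate into a terminal fusion conv.
    """

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5,
                 cib_e: float = 2.0, shortcut: bool = True):
        super().__init__()
        if n < 1:
            raise ValueError("n_blocks must be >= 1")
        self.c = int(c2 * e)
        self.cv1 = Conv(c1, 2 * self.c, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1)
        self.m = ModuleList(CIB(self.c, self.c, e=cib_e, shortcut=shortcut) for _ in range(n))

    def forward(self, x):
        y = chunk(self.cv1(x), 2, 1)
        for m in self.m:
            y.append(m(y[-1]))
        return self.cv2(cat(y, 1))


class GatedCNNBlock(Module):
    """Gated convolution block: Y = (TokenMixer(X'W1) (*) silu(X'W2)) W3 + X.

    X' = Norm(X) (channel batch norm); W1/W2/W3 are bias-free 1x1 convolutions;
    the token mixer cascades ``mixer_depth`` depthwise ``mixer_kernel`` convs
    over the W1 projection while the W2 path provides SiLU spatial gating.
    Output shape equals input shape (residual block).
    """

    def __init__(self, dim: int, hidden: int | None = None, expansion: float = 8 / 3,
                 mixer_depth: int = 2, mixer_kernel: int = 7):
        super().__init__()
        from .layers import BatchNorm2d
        h = hidden if hidden is not None else int(dim * expansion)
        self.norm = BatchNorm2d(dim)
        self.w1 = Conv2d(dim, h, 1, bias=False)
        self.w2 = Conv2d(dim, h, 1, bias=False)
        self.mixer = Sequential(*[
            Conv2d(h, h, mixer_kernel, 1, mixer_kernel // 2, g=h, bias=False)
            for _ in range(mixer_depth)
        ])
        self.w3 = Conv2d(h, dim, 1, bias=False)

    def forward(self, x):
        xn = self.norm(x)
        return self.w3(self.mixer(self.w1(xn)) * self.w2(xn).silu()) + x


class C3k2Mambaout(Module):
    """C3k2-style wrapper around gated CNN blocks.

    A 1x1 split conv reduces to the hidden width, ``n`` gated blocks run in
    series with intermediates retained, and the concatenated branches fuse
    through a terminal 1x1 conv. Every gated block carries its own residual
    connection.
    """

    #: hidden width of the gated blocks at the published P5 placement; solved
    #: from the printed parameter budget (the paper states no widths).
    DEFAULT_HIDDEN = 1023

    def __init__(self, c1: int, c2: int, n: int = 1, e: float = 0.5,
                 hidden: int | None = DEFAULT_HIDDEN, mixer_depth: int = 2,
                 mixer_kernel: int = 7):
        super().__init__()
        if n < 1:
            raise ValueError("n gated blocks must be >= 1")
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv((1 + n) * c_, c2, 1)
        self.m = ModuleList(
            GatedCNNBlock(c_, hidden=hidden, mixer_depth=mixer_depth,
                          mixer_kernel=mixer_kernel)
            for _ in range(n)
        )

    def forward(self, x):
        y = [self.cv1(x)]
        for m in self.m:
            y.append(m(y[-1]))
        return self.cv2(cat(y, 1))


# -- head -------------------------------------------------------------------

class DFL(Module):
    """Distribution focal projection: softmax over bins -> expected distance."""

    def __init__(self, c1: int = 16):
        super().__init__()
        self.c1 = c1
        self.weight = Parameter(np.arange(c1, dtype=np.float32).reshape(1, c1, 1, 1),
                                requires_grad=False)

    def forward(self, x: Tensor) -> Tensor:
        # x: (N, 4*c1, A) -> (N, 4, A) expected distances
        n, _, a = x.shape
        x = x.reshape(n, 4, self.c1, a).softmax(axis=2)
        bins = Tensor(self.weight.data.reshape(1, 1, self.c1, 1))
        return (x * bins).sum(axis=2)


class Detect(Module):
    """Decoupled anchor-free head: box-regression and classification branches."""

    def __init__(self, nc: int, ch: tuple[int, ...], reg_max: int = 16,
                 strides: tuple[int, ...] = (8, 16, 32)):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.strides = strides
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.cv2 = ModuleList(
            Sequential(Conv(x, c2, 3), Conv(c2, c2, 3), Conv2d(c2, 4 * reg_max, 1))
            for x in ch
        )
        self.cv3 = ModuleList(
            Sequential(
                Sequential(DWConv(x, x, 3), Conv(x, c3, 1)),
                Sequential(DWConv(c3, c3, 3), Conv(c3, c3, 1)),
                Conv2d(c3, nc, 1),
            )
            for x in ch
        )
        self.dfl = DFL(reg_max)
        self._bias_init()

    def _bias_init(self):
        for s, reg, cls in zip(self.strides, self.cv2, self.cv3):
            reg[2].bias.data[:] = 1.0
            cls[2].bias.data[:] = float(np.log(5 / self.nc / (640 / s) ** 2))

    def forward(self, feats: list[Tensor]) -> list[Tensor]:
        outs = [cat([reg(x), cls(x)], 1) for x, reg, cls in zip(feats, self.cv2, self.cv3)]
        from .layers import FlopProfile
        prof = FlopProfile.active
        if prof is not None:  # the DFL projection applied to every anchor at inference
            anchors = sum(o.shape[0] * o.shape[2] * o.shape[3] for o in outs)
            prof.add_macs(4 * anchors * self.reg_max)
        return outs

    def decode(self, outputs: list[Tensor], conf_thresh: float = 0.25) -> list[list]:
        """Numpy-only inference decode -> per-image [(class, (x1,y1,x2,y2), score)].

        Coordinates are normalized by the inferred input size.
        """
        batch = outputs[0].shape[0]
        imgsz = outputs[0].shape[2] * self.strides[0]
        results: list[list] = [[] for _ in range(batch)]
        for out, stride in zip(outputs, self.strides):
            data = out.data
            n, _, h, w = data.shape
            reg = data[:, :4 * self.reg_max].reshape(n, 4, self.reg_max, h * w)
            z = reg - reg.max(axis=2, keepdims=True)
            e = np.exp(z)
            dist = (e / e.sum(axis=2, keepdims=True) *
                    np.arange(self.reg_max).reshape(1, 1, -1, 1)).sum(axis=2)
            cls = 1.0 / (1.0 + np.exp(-data[:, 4 * self.reg_max:]))
            gy, gx = np.meshgrid(np.arange(h) + 0.5, np.arange(w) + 0.5, indexing="ij")
            cxg, cyg = gx.ravel(), gy.ravel()
            x1 = (cxg - dist[:, 0]) * stride
            y1 = (cyg - dist[:, 1]) * stride
            x2 = (cxg + dist[:, 2]) * stride
            y2 = (cyg + dist[:, 3]) * stride
            for b in range(n):
                scores = cls[b].reshape(self.nc, h * w)
                best_c = scores.argmax(axis=0)
                best_s = scores.max(axis=0)
                keep = best_s >= conf_thresh
                for i in np.where(keep)[0]:
                    results[b].append((
                        int(best_c[i]),
                        (x1[b, i] / imgsz, y1[b, i] / imgsz, x2[b, i] / imgsz, y2[b, i] / imgsz),
                        float(best_s[i]),
                    ))
        return results
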