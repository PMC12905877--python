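"""Module system and primitive layers (conv, batch norm, composite Conv block).

Initialization mirrors common convnet defaults (uniform +-1/sqrt(fan_in));
all randomness flows through :func:`seed_rng`, so identical seeds build
byte-identical models.
"""

from __future__ import annotations

import numpy as np

from .core import Tensor, batch_norm, conv2d

_RNG = np.random.default_rng(0)


def seed_rng(seed: int) -> None:
    """Reset the global initialization RNG (call before building a model)."""
    global _RNG
    _RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data, requires_grad: bool = True):
        super().__init__(data, requires_grad=requires_grad)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    yield from sub.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, ModuleList):
                for sub in value:
                    yield from sub.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- state --------------------------------------------------------------

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters(prefix)}
        for name, value in vars(self).items():
            if isinstance(value, BatchNorm2d):
                out[f"{prefix}{name}.running_mean"] = value.running_mean.copy()
                out[f"{prefix}{name}.running_var"] = value.running_var.copy()
            elif isinstance(value, Module):
                for k, v in value.state_dict(f"{prefix}{name}.").items():
                    if k not in out:
                        out[k] = v
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    for k, v in sub.state_dict(f"{prefix}{name}.{i}.").items():
                        if k not in out:
                            out[k] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        params = dict(self.named_parameters(prefix))
        for name, p in params.items():
            p.data[...] = state[name]
        for name, value in vars(self).items():
            if isinstance(value, BatchNorm2d):
                value.running_mean[...] = state[f"{prefix}{name}.running_mean"]
                value.running_var[...] = state[f"{prefix}{name}.running_var"]
            elif isinstance(value, Module) and not isinstance(value, BatchNorm2d):
                value.load_state_dict(state, f"{prefix}{name}.")
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    sub.load_state_dict(state, f"{prefix}{name}.{i}.")


class ModuleList(list):
    pass


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.layers = ModuleList(mods)

    def forward(self, x):
        for m in self.layers:
            x = m(x)
        return x

    def __getitem__(self, i):
        return self.layers[i]


# -- profiling --------------------------------------------------------------

class FlopProfile:
    """Accumulates multiply-accumulate and elementwise op counts per label."""

    active: "FlopProfile | None" = None

    def __init__(self, count_matmul: bool = False):
        self.macs: dict[str, int] = {}
        self.elementwise: dict[str, int] = {}
        self.matmuls: dict[str, int] = {}
        self.count_matmul = count_matmul
        self.label = ""

    def add_macs(self, n: int) -> None:
        self.macs[self.label] = self.macs.get(self.label, 0) + int(n)

    def add_elementwise(self, n: int) -> None:
        self.elementwise[self.label] = self.elementwise.get(self.label, 0) + int(n)

    def add_matmul_macs(self, n: int) -> None:
        self.matmuls[self.label] = self.matmuls.get(self.label, 0) + int(n)

    def __enter__(self):
        FlopProfile.active = self
        return self

    def __exit__(self, *exc):
        FlopProfile.active = None


# -- primitives -------------------------------------------------------------

def autopad(k: int, p: int | None = None) -> int:
    return k // 2 if p is None else p


class Conv2d(Module):
    """Plain convolution (optionally biased), uniform +-1/sqrt(fan_in) init."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None,
                 g: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.groups = s, autopad(k, p), g
        fan_in = c1 // g * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(_RNG.uniform(-bound, bound, (c2, c1 // g, k, k)))
        self.bias = Parameter(_RNG.uniform(-bound, bound, c2)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)
        prof = FlopProfile.active
        if prof is not None:
            c2, cg, k, _ = self.weight.shape
            n, _, ho, wo = out.shape
            prof.add_macs(n * ho * wo * c2 * cg * k * k)
        return out


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(c))
        self.bias = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        prof = FlopProfile.active
        if prof is not None:
            prof.add_elementwise(2 * int(np.prod(x.shape)))
        return batch_norm(x, self.weight, self.bias, self.running_mean,
                          self.running_var, self.training, self.momentum, self.eps)


def _act_silu(x: Tensor) -> Tensor:
    prof = FlopProfile.active
    if prof is not None:
        prof.add_elementwise(int(np.prod(x.shape)))
    return x.silu()


class Conv(Module):
    """conv + batch norm + optional SiLU, the detector's workhorse block."""

    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, p: int | None = None,
                 g: int = 1, act: bool = True):
        super().__init__()
        self.conv = Conv2d(c1, c2, k, s, p, g, bias=False)
        self.bn = BatchNorm2d(c2)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return _act_silu(y) if self.act else y


class DWConv(Conv):
    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1, act: bool = True):
        super().__init__(c1, c2, k, s, g=np.gcd(c1, c2), act=act)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        from .core import upsample_nearest2x
        out = upsample_nearest2x(x)
        prof = FlopProfile.active
        if prof is not None:
            prof.add_elementwise(int(np.prod(out.shape)))
        return out
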