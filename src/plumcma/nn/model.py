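"""YOLO-CMA assembly, ablation variants and complexity accounting.

The baseline is an attention-augmented CSP single-stage detector at nano
scale (grouped early downsampling, area-attention stages at P4/P5, PAN neck,
decoupled anchor-free head, strides 8/16/32). Two independent flags build the
ablation grid:

* ``use_c3k2_mambaout`` -- the deepest backbone stage (P5) becomes a
  :class:`~plumcma.nn.blocks.C3k2Mambaout` wrapper of gated CNN blocks.
* ``use_c2fcib`` -- the neck fusion unit feeding the P5 head (the deepest
  unit of the fusion pipeline) becomes a :class:`~plumcma.nn.blocks.C2fCIB`.

With both flags off the unmodified baseline is reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import A2C2f, C2fCIB, C3k2, C3k2Mambaout, Detect
from .core import Tensor, cat
from .layers import Conv, FlopProfile, Module, ModuleList, Upsample2x, seed_rng

STRIDES = {"P3": 8, "P4": 16, "P5": 32}


@dataclass(frozen=True)
class ModelConfig:
    num_classes: int = 5
    input_size: int = 416
    depth: float = 0.5
    width: float = 0.25
    use_c2fcib: bool = False
    use_c3k2_mambaout: bool = False
    seed: int = 0
    # contributed-module internals (defaults reproduce the published budget)
    mambaout_hidden: int = C3k2Mambaout.DEFAULT_HIDDEN
    mambaout_blocks: int = 1
    mixer_depth: int = 2
    mixer_kernel: int = 7
    c2fcib_blocks: int = 2
    cib_expansion: float = 2.0

    def __post_init__(self) -> None:
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if (self.depth, self.width) != (0.5, 0.25):
            raise ValueError(
                f"unsupported multiplier set (depth={self.depth}, width={self.width}); "
                "only the nano scale (0.5, 0.25) is provided"
            )


@dataclass
class ComplexityReport:
    total: float
    breakdown: dict[str, float] = field(default_factory=dict)
    input_size: int | None = None
    convention: str = ""

    def __post_init__(self) -> None:
        if self.breakdown:
            assert abs(self.total - sum(self.breakdown.values())) < 1e-6


class _Concat(Module):
    def __init__(self, sources: tuple[int, ...]):
        super().__init__()
        self.sources = sources

    def forward(self, xs: list[Tensor]) -> Tensor:
        return cat(xs, 1)


class YoloCMA(Module):
    """Graph-structured detector; layer connectivity mirrors the nano baseline."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        seed_rng(cfg.seed)
        self.cfg = cfg
        nc = cfg.num_classes

        if cfg.use_c3k2_mambaout:
            p5_backbone = C3k2Mambaout(256, 256, n=cfg.mambaout_blocks,
                                       hidden=cfg.mambaout_hidden,
                                       mixer_depth=cfg.mixer_depth,
                                       mixer_kernel=cfg.mixer_kernel)
        else:
            p5_backbone = A2C2f(256, 256, n=2, a2=True, area=1)
        if cfg.use_c2fcib:
            p5_fusion = C2fCIB(384, 256, n=cfg.c2fcib_blocks, cib_e=cfg.cib_expansion)
        else:
            p5_fusion = C3k2(384, 256, n=1, c3k=True)

        # (module, input spec): -1 = previous output, ints = saved layer outputs
        self.layers = ModuleList([
            Conv(3, 16, 3, 2),                         # 0  P1/2
            Conv(16, 32, 3, 2, g=2),                   # 1  P2/4
            C3k2(32, 64, n=1, c3k=False, e=0.25),      # 2
            Conv(64, 64, 3, 2, g=4),                   # 3  P3/8
            C3k2(64, 128, n=1, c3k=False, e=0.25),     # 4
            Conv(128, 128, 3, 2),                      # 5  P4/16
            A2C2f(128, 128, n=2, a2=True, area=4),     # 6
            Conv(128, 256, 3, 2),                      # 7  P5/32
            p5_backbone,                               # 8
            Upsample2x(),                              # 9
            _Concat((-1, 6)),                          # 10
            A2C2f(384, 128, n=1, a2=False),            # 11
            Upsample2x(),                              # 12
            _Concat((-1, 4)),                          # 13
            A2C2f(256, 64, n=1, a2=False),             # 14 P3 head input
            Conv(64, 64, 3, 2),                        # 15
            _Concat((-1, 11)),                         # 16
            A2C2f(192, 128, n=1, a2=False),            # 17 P4 head input
            Conv(128, 128, 3, 2),                      # 18
            _Concat((-1, 8)),                          # 19
            p5_fusion,                                 # 20 P5 head input
            Detect(nc, (64, 128, 256)),                # 21
        ])
        self._save = {4, 6, 8, 11, 14, 17, 20}

    def forward(self, x: Tensor) -> list[Tensor]:
        saved: dict[int, Tensor] = {}
        prof = FlopProfile.active
        out = x
        for i, layer in enumerate(self.layers):
            if prof is not None:
                prof.label = f"layer{i}:{type(layer).__name__}"
            if isinstance(layer, _Concat):
                parts = [out if s == -1 else saved[s] for s in layer.sources]
                out = layer(parts)
            elif isinstance(layer, Detect):
                out = layer([saved[14], saved[17], saved[20]])
            else:
                out = layer(out)
            if i in self._save:
                saved[i] = out
        return out  # three per-scale prediction maps

    @property
    def detect(self) -> Detect:
        return self.layers[-1]


def build_yolocma(cfg: ModelConfig | None = None, **kwargs) -> YoloCMA:
    if cfg is None:
        cfg = ModelConfig(**kwargs)
    return YoloCMA(cfg)


def save_checkpoint(model: YoloCMA, path) -> None:
    """Serialize config + weights in numpy's standard .npz container."""
    import io
    import yaml as _yaml
    from dataclasses import asdict
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        _yaml.safe_dump(asdict(model.cfg)).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> YoloCMA:
    import yaml as _yaml
    with np.load(path) as archive:
        raw = {k: archive[k] for k in archive.files}
    cfg = ModelConfig(**_yaml.safe_load(raw.pop("__config__").tobytes().decode()))
    model = YoloCMA(cfg)
    model.load_state_dict(raw)
    return model


def config_to_yaml(cfg: ModelConfig, path) -> None:
    from dataclasses import asdict
    import yaml as _yaml
    from pathlib import Path
    Path(path).write_text(_yaml.safe_dump(asdict(cfg), sort_keys=False))


def config_from_yaml(path) -> ModelConfig:
    import yaml as _yaml
    from pathlib import Path
    return ModelConfig(**_yaml.safe_load(Path(path).read_text()))


ABLATION_VARIANTS = {
    "baseline": dict(use_c2fcib=False, use_c3k2_mambaout=False),
    "c2fcib": dict(use_c2fcib=True, use_c3k2_mambaout=False),
    "mambaout": dict(use_c2fcib=False, use_c3k2_mambaout=True),
    "cma": dict(use_c2fcib=True, use_c3k2_mambaout=True),
}


def count_params(model: YoloCMA) -> ComplexityReport:
    breakdown = {
        f"layer{i}:{type(layer).__name__}": float(layer.num_params())
        for i, layer in enumerate(model.layers)
    }
    return ComplexityReport(total=float(sum(breakdown.values())), breakdown=breakdown,
                            convention="all parameters incl. frozen DFL projection")


def count_flops(model: YoloCMA, input_size: int | None = None,
                include_elementwise: bool = False,
                include_attention_matmul: bool = False) -> ComplexityReport:
    """Per-layer FLOP accounting at ``input_size`` (multiply-accumulate = 2 ops).

    By default only weight-bearing layers (convolutions) are counted, which is
    the convention detector-summary tools print. ``include_attention_matmul``
    adds the attention q/k/v matmul work and ``include_elementwise`` adds
    normalization, activation and upsampling element ops.
    """
    size = input_size or model.cfg.input_size
    if size % 32 != 0:
        raise ValueError("input size must be a multiple of 32")
    was_training = model.training
    model.eval()
    with FlopProfile() as prof:
        model(Tensor(np.zeros((1, 3, size, size), dtype=np.float32)))
    model.train(was_training)
    breakdown = {}
    for label in set(prof.macs) | set(prof.elementwise) | set(prof.matmuls):
        flops = 2.0 * prof.macs.get(label, 0)
        if include_attention_matmul:
            flops += 2.0 * prof.matmuls.get(label, 0)
        if include_elementwise:
            flops += prof.elementwise.get(label, 0)
        if flops:
            breakdown[label] = flops
    conv = "2*MACs (conv)" + (" + matmul" if include_attention_matmul else "") + \
        (" + elementwise" if include_elementwise else "")
    return ComplexityReport(total=float(sum(breakdown.values())), breakdown=breakdown,
                            input_size=size, convention=conv)


def std_conv_flops(h: int, w: int, c: int) -> float:
    """Printed closed form for a 3x3 standard convolution stage: (9/2) H W C^2."""
    if min(h, w, c) < 1:
        raise ValueError("dimensions must be positive")
    return 4.5 * h * w * c * c


def dsc_flops(h: int, w: int, c: int) -> float:
    """Printed closed form for the separable decomposition: 2 H W C^2 + (9/2) H W C."""
    if min(h, w, c) < 1:
        raise ValueError("dimensions must be positive")
    return 2.0 * h * w * c * c + 4.5 * h * w * c


def _wh_iou(wh: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """IoU between box sizes assuming aligned top-left corners: (n, k)."""
    inter = np.minimum(wh[:, None, 0], centers[None, :, 0]) * \
        np.minimum(wh[:, None, 1], centers[None, :, 1])
    union = wh[:, 0:1] * wh[:, 1:2] + (centers[:, 0] * centers[:, 1])[None, :] - inter
    return inter / np.maximum(union, 1e-12)


def kmeans_anchors(boxes, k: int, seed: int = 0, iters: int = 300) -> np.ndarray:
    """K-means over (w, h) pairs with 1 - IoU distance; returns k prior sizes.

    Deterministic under ``seed``; raises if fewer boxes than clusters.
    """
    wh = np.asarray(boxes, dtype=np.float64).reshape(-1, 2)
    if len(wh) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(wh)}")
    rng = np.random.default_rng(seed)
    centers = wh[rng.choice(len(wh), size=k, replace=False)].copy()
    assign = np.full(len(wh), -1)
    for _ in range(iters):
        d = 1.0 - _wh_iou(wh, centers)
        new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = wh[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return centers[order]
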