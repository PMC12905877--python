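"""Smoke-training: a simplified dense detection loss plus Adam.

This intentionally replaces the full published training stack (mosaic,
randaugment, task-aligned assignment, AMP, ...) with a minimal center-cell
assigner and a three-term loss -- IoU box loss on DFL-decoded distances,
binary cross-entropy classification, and distribution-focal regression --
weighted by the configurable box/cls/dfl scalars (defaults 7.5 / 0.5 / 1.5).
Its only job is to demonstrate that the assembled model trains: gradients
flow and a small fixed batch is overfit within a few hundred steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Tensor
from .model import YoloCMA


@dataclass(frozen=True)
class LossWeights:
    box: float = 7.5
    cls: float = 0.5
    dfl: float = 1.5


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _bce_with_logits(x: Tensor, target: np.ndarray) -> Tensor:
    t = Tensor(target)
    ax = x.maximum(-x)  # |x|
    return x.relu() - x * t + ((-ax).exp() + 1.0).log()


def assign_targets(targets, shapes, strides, imgsz: int, reg_max: int = 16):
    """Center-cell assignment: each box claims one cell at a size-chosen scale.

    ``targets``: per-image list of (class_id, cx, cy, w, h) normalized.
    Returns per-scale positive indices, target distances (stride units) and
    one-hot class grids.
    """
    pos = [([], [], [], [], []) for _ in strides]  # b, gy, gx, dist, cls
    for b, boxes in enumerate(targets):
        for class_id, cx, cy, w, h in boxes:
            side = max(w, h) * imgsz
            scale = 0 if side < 4 * strides[0] else (1 if side < 4 * strides[1] else 2)
            _, _, gh, gw = shapes[scale]
            s = strides[scale]
            gx = min(int(cx * gw), gw - 1)
            gy = min(int(cy * gh), gh - 1)
            ax, ay = gx + 0.5, gy + 0.5  # anchor point in grid units
            x1, y1 = cx * imgsz / s, cy * imgsz / s
            bw, bh = w * imgsz / s, h * imgsz / s
            dist = np.array([
                ax - (x1 - bw / 2), ay - (y1 - bh / 2),
                (x1 + bw / 2) - ax, (y1 + bh / 2) - ay,
            ])
            if (dist <= 0).any():  # degenerate: box does not cover its cell center
                dist = np.clip(dist, 0.05, None)
            dist = np.clip(dist, 0, reg_max - 1 - 0.01)
            pb, py, px, pd, pc = pos[scale]
            pb.append(b)
            py.append(gy)
            px.append(gx)
            pd.append(dist)
            pc.append(class_id)
    return pos


def detection_loss(model: YoloCMA, outputs, targets, imgsz: int,
                   weights: LossWeights = LossWeights()):
    """Weighted box-IoU + BCE classification + distribution-focal loss."""
    nc = model.cfg.num_classes
    reg_max = model.detect.reg_max
    strides = model.detect.strides
    shapes = [o.shape for o in outputs]
    pos = assign_targets(targets, shapes, strides, imgsz, reg_max)
    n_pos = sum(len(p[0]) for p in pos)

    zero = Tensor(np.float32(0.0))
    loss_box, loss_cls, loss_dfl = zero, zero, zero
    bins = Tensor(np.arange(reg_max, dtype=np.float32).reshape(1, 1, reg_max))

    for scale, out in enumerate(outputs):
        n, c, gh, gw = out.shape
        pb, py, px, pd, pc = pos[scale]
        cls_logits = out[:, 4 * reg_max:, :, :]
        cls_target = np.zeros((n, nc, gh, gw), dtype=np.float32)
        if pb:
            cls_target[pb, pc, py, px] = 1.0
        loss_cls = loss_cls + _bce_with_logits(cls_logits, cls_target).sum()

        if not pb:
            continue
        nhwc = out.transpose(0, 2, 3, 1)
        vecs = nhwc[(np.array(pb), np.array(py), np.array(px))]  # (P, C)
        reg = vecs[:, :4 * reg_max].reshape(len(pb), 4, reg_max)
        probs = reg.softmax(axis=2)
        dist_pred = (probs * bins).sum(axis=2)  # (P, 4)
        gt = np.stack(pd).astype(np.float32)

        gl, gt_, gr, gb = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
        dl = dist_pred[:, 0]
        dt = dist_pred[:, 1]
        dr = dist_pred[:, 2]
        db = dist_pred[:, 3]
        iw = dl.minimum(Tensor(gl)) + dr.minimum(Tensor(gr))
        ih = dt.minimum(Tensor(gt_)) + db.minimum(Tensor(gb))
        inter = iw.clamp_min(0.0) * ih.clamp_min(0.0)
        area_p = (dl + dr) * (dt + db)
        area_g = Tensor((gl + gr) * (gt_ + gb))
        iou = inter / (area_p + area_g - inter + 1e-9)
        loss_box = loss_box + (1.0 - iou).sum()

        logp = probs.clamp_min(1e-9).log()  # (P, 4, reg_max)
        tl = np.floor(gt).astype(np.int64)
        tr = np.minimum(tl + 1, reg_max - 1)
        wl = (tr - gt).astype(np.float32)
        wr = (1.0 - wl).astype(np.float32)
        pidx = np.repeat(np.arange(len(pb)), 4)
        sidx = np.tile(np.arange(4), len(pb))
        left = logp[(pidx, sidx, tl.ravel())] * Tensor(-wl.ravel())
        right = logp[(pidx, sidx, tr.ravel())] * Tensor(-wr.ravel())
        loss_dfl = loss_dfl + (left + right).sum()

    denom = max(n_pos, 1)
    return (weights.box * loss_box * (1.0 / denom)
            + weights.cls * loss_cls * (1.0 / denom)
            + weights.dfl * loss_dfl * (1.0 / (4 * denom)))


def train_smoke(model: YoloCMA, images: np.ndarray, targets, steps: int = 200,
                lr: float = 0.01, seed: int = 0,
                weights: LossWeights = LossWeights()) -> list[float]:
    """Run ``steps`` gradient steps on one fixed batch; return the loss trace.

    ``images``: (N, 3, H, W) float32 in [0, 1]. ``targets``: per-image list of
    (class_id, cx, cy, w, h). Aborts with diagnostics on a non-finite loss.
    Deterministic: the only randomness is the model's build seed.
    """
    del seed  # the forward/backward pass is already deterministic
    imgsz = images.shape[2]
    model.train()
    opt = Adam(model.parameters(), lr=lr)
    trace: list[float] = []
    x = Tensor(images.astype(np.float32))
    for step in range(steps):
        outputs = model(x)
        loss = detection_loss(model, outputs, targets, imgsz, weights)
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"non-finite loss {value} at step {step}; "
                f"last finite losses: {trace[-5:]}"
            )
        trace.append(value)
        if lr > 0:
            model.zero_grad()
            loss.backward()
            opt.step()
    return trace
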