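"""Detection matching and evaluation: P, R, F1, AP, mAP50, mAP50-95.

Matching is per image and per class, greedy in descending confidence, one
ground truth per detection. AP uses all-point (precision-envelope)
interpolation of the PR curve by default; the 101-point variant is available
behind a flag. mAP50-95 averages AP over IoU thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

IOU_SWEEP = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class Detection:
    image_id: str
    class_id: int
    box: tuple[float, float, float, float]  # normalized corners x1, y1, x2, y2
    confidence: float

    def __post_init__(self) -> None:
        x1, y1, x2, y2 = self.box
        if x2 < x1 or y2 < y1:
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class MatchResult:
    """Confidence-ordered TP/FP flags for one (image, class) pool plus FN count."""

    flags: list[bool] = field(default_factory=list)  # True = TP, ordered by confidence desc
    confidences: list[float] = field(default_factory=list)
    n_truths: int = 0

    @property
    def tp(self) -> int:
        return sum(self.flags)

    @property
    def fp(self) -> int:
        return len(self.flags) - self.tp

    @property
    def fn(self) -> int:
        return self.n_truths - self.tp


def iou(box_a, box_b) -> float:
    """Intersection over union of two corner-format boxes."""
    ax1, ay1, ax2, ay2 = box_a
    bx1, by1, bx2, by2 = box_b
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax2 - ax1) * (ay2 - ay1) + (bx2 - bx1) * (by2 - by1) - inter
    return inter / union if union > 0 else 0.0


def match_detections(dets, truths, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching within a single (image, class) pool.

    ``dets``: list of (box, confidence); ``truths``: list of boxes. Each
    detection, in descending confidence, claims the unmatched truth with the
    highest IoU if that IoU reaches the threshold.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    taken = [False] * len(truths)
    flags, confs = [], []
    for i in order:
        box, conf = dets[i]
        best_j, best_iou = -1, iou_threshold
        for j, tbox in enumerate(truths):
            if taken[j]:
                continue
            v = iou(box, tbox)
            if v >= best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            taken[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
        confs.append(conf)
    return MatchResult(flags=flags, confidences=confs, n_truths=len(truths))


def precision(tp: int, fp: int) -> float:
    return tp / (tp + fp) if tp + fp > 0 else 0.0


def recall(tp: int, fn: int) -> float:
    return tp / (tp + fn) if tp + fn > 0 else 0.0


def f1(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if p + r > 0 else 0.0


def average_precision(flags, n_truths: int, interpolation: str = "all") -> float:
    """Area under the precision envelope over recall.

    ``flags`` are confidence-sorted TP/FP booleans pooled over all images.
    ``interpolation``: 'all' (exact, default) or '101' (COCO-style grid).
    """
    if n_truths == 0 or len(flags) == 0:
        return 0.0
    flags = np.asarray(flags, dtype=bool)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    rec = tp_cum / n_truths
    prec = tp_cum / np.maximum(tp_cum + fp_cum, 1)

    rec = np.concatenate([[0.0], rec, [1.0]])
    prec = np.concatenate([[1.0], prec, [0.0]])
    for i in range(len(prec) - 2, -1, -1):  # precision envelope
        prec[i] = max(prec[i], prec[i + 1])
    if interpolation == "all":
        idx = np.where(rec[1:] != rec[:-1])[0]
        return float(np.sum((rec[idx + 1] - rec[idx]) * prec[idx + 1]))
    if interpolation == "101":
        # right-continuous envelope lookup: precision of the first recall >= r
        grid = np.linspace(0, 1, 101)
        idx = np.searchsorted(rec, grid, side="left")
        return float(prec[np.minimum(idx, len(prec) - 1)].mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


@dataclass
class PRCurve:
    recalls: np.ndarray
    precisions: np.ndarray


@dataclass
class EvalReport:
    per_class: dict[int, dict[str, float]]
    mean_precision: float
    mean_recall: float
    mean_f1: float
    map50: float
    map50_95: float

    def as_dict(self) -> dict:
        return {
            "per_class": {int(k): dict(v) for k, v in self.per_class.items()},
            "precision": self.mean_precision,
            "recall": self.mean_recall,
            "f1": self.mean_f1,
            "mAP50": self.map50,
            "mAP50_95": self.map50_95,
        }


def _class_ap(dets, truths, threshold: float, interpolation: str) -> float:
    """Pool matches over images for one class and compute AP at one IoU."""
    flags_conf: list[tuple[float, bool]] = []
    n_truths = 0
    images = set(truths) | set(dets)
    for img in images:
        res = match_detections(dets.get(img, []), truths.get(img, []), threshold)
        flags_conf.extend(zip(res.confidences, res.flags))
        n_truths += res.n_truths
    flags_conf.sort(key=lambda t: -t[0])
    return average_precision([f for _, f in flags_conf], n_truths, interpolation)


def _class_prf(dets, truths, threshold: float, fixed_conf: float | None):
    """P/R/F1 for one class, either at a fixed confidence or at the F1-max point."""
    pooled: list[tuple[float, bool]] = []
    n_truths = 0
    for img in set(truths) | set(dets):
        res = match_detections(dets.get(img, []), truths.get(img, []), threshold)
        pooled.extend(zip(res.confidences, res.flags))
        n_truths += res.n_truths
    pooled.sort(key=lambda t: -t[0])
    if not pooled:
        return 0.0, 0.0, 0.0

    best = (0.0, 0.0, 0.0)
    tp = fp = 0
    for conf, flag in pooled:
        if fixed_conf is not None and conf < fixed_conf:
            break
        tp += int(flag)
        fp += int(not flag)
        p = precision(tp, fp)
        r = recall(tp, n_truths - tp)
        f = f1(p, r)
        if fixed_conf is not None or f >= best[2]:
            best = (p, r, f)
    return best


def evaluate(detections, ground_truth, classes=None, interpolation: str = "all",
             fixed_confidence: float | None = None) -> EvalReport:
    """Full evaluation protocol over the IoU sweep 0.50:0.05:0.95.

    ``detections``: iterable of Detection. ``ground_truth``: iterable of
    (image_id, class_id, corner box). P/R/F1 are reported at IoU 0.50, either
    at ``fixed_confidence`` or (default) the confidence maximizing F1.
    """
    if classes is None:
        classes = sorted({c for _, c, _ in ground_truth} | {d.class_id for d in detections})
        if not classes:
            classes = [0]

    dets_by_class: dict[int, dict[str, list]] = {c: {} for c in classes}
    truths_by_class: dict[int, dict[str, list]] = {c: {} for c in classes}
    for d in detections:
        if d.class_id in dets_by_class:
            dets_by_class[d.class_id].setdefault(d.image_id, []).append((d.box, d.confidence))
    for img, c, box in ground_truth:
        if c in truths_by_class:
            truths_by_class[c].setdefault(img, []).append(box)

    per_class: dict[int, dict[str, float]] = {}
    for c in classes:
        aps = [_class_ap(dets_by_class[c], truths_by_class[c], t, interpolation) for t in IOU_SWEEP]
        p, r, f = _class_prf(dets_by_class[c], truths_by_class[c], 0.5, fixed_confidence)
        per_class[c] = {
            "precision": p, "recall": r, "f1": f,
            "ap50": aps[0], "ap50_95": float(np.mean(aps)),
        }

    n = len(classes)
    return EvalReport(
        per_class=per_class,
        mean_precision=sum(v["precision"] for v in per_class.values()) / n,
        mean_recall=sum(v["recall"] for v in per_class.values()) / n,
        mean_f1=sum(v["f1"] for v in per_class.values()) / n,
        map50=sum(v["ap50"] for v in per_class.values()) / n,
        map50_95=sum(v["ap50_95"] for v in per_class.values()) / n,
    )
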