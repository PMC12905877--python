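"""YOLO-format label IO, dataset manifests, class statistics and stratified splits.

Boxes are stored in the normalized center format ``class cx cy w h`` used by
single-stage detector tooling; one ``.txt`` label file per image. A manifest is
a CSV with columns ``path,class_id,split`` binding each image to its record
class and split assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CLASS_NAMES = ("diseased", "insect", "bird_pecked", "cracked", "normal")
NUM_CLASSES = len(CLASS_NAMES)
SPLITS = ("train", "val", "test", "unassigned")


@dataclass(frozen=True)
class BBox:
    """A normalized center-format bounding box with its class id."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not 0 <= self.class_id < NUM_CLASSES:
            raise ValueError(f"class_id {self.class_id} outside [0, {NUM_CLASSES - 1}]")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside unit square")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box size ({self.w}, {self.h}) outside (0, 1]")

    def corners(self) -> tuple[float, float, float, float]:
        """Return (x1, y1, x2, y2) clipped to the unit square."""
        x1 = max(0.0, self.cx - self.w / 2)
        y1 = max(0.0, self.cy - self.h / 2)
        x2 = min(1.0, self.cx + self.w / 2)
        y2 = min(1.0, self.cy + self.h / 2)
        return x1, y1, x2, y2

    @classmethod
    def from_corners(cls, class_id: int, x1: float, y1: float, x2: float, y2: float) -> "BBox":
        return cls(class_id, (x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


@dataclass
class ClassDistribution:
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, class_id: int) -> int:
        return self.counts.get(class_id, 0)


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.7
    val: float = 0.2
    test: float = 0.1

    def __post_init__(self) -> None:
        s = self.train + self.val + self.test
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"split ratios sum to {s}, expected 1")
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("split ratios must be positive")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.train, self.val, self.test)


@dataclass
class Manifest:
    """Ordered list of (image path, class id, split) records."""

    records: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for path, class_id, split in self.records:
            if path in seen:
                raise ValueError(f"duplicate manifest path: {path}")
            seen.add(path)
            if not 0 <= class_id < NUM_CLASSES:
                raise ValueError(f"invalid class id {class_id} for {path}")
            if split not in SPLITS:
                raise ValueError(f"invalid split {split!r} for {path}")

    def __len__(self) -> int:
        return len(self.records)

    def paths(self) -> list[str]:
        return [r[0] for r in self.records]

    def subset(self, split: str) -> "Manifest":
        return Manifest([r for r in self.records if r[2] == split])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.records, columns=["path", "class_id", "split"])
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Manifest":
        df = pd.read_csv(path)
        return cls([(str(p), int(c), str(s)) for p, c, s in zip(df["path"], df["class_id"], df["split"])])


def parse_label_line(line: str, lineno: int) -> BBox:
    parts = line.split()
    if len(parts) != 5:
        raise ValueError(f"line {lineno}: expected 5 fields 'class cx cy w h', got {len(parts)}")
    try:
        class_id = int(parts[0])
        vals = [float(v) for v in parts[1:]]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc
    return BBox(class_id, *vals)


def read_labels(path: str | Path) -> list[BBox]:
    """Parse a YOLO label file into a list of boxes.

    Raises ``ValueError`` naming the offending line for malformed input.
    """
    boxes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            boxes.append(parse_label_line(line, lineno))
    return boxes


def write_labels(boxes: Iterable[BBox], path: str | Path) -> None:
    """Write boxes as YOLO label lines with 6-decimal coordinates."""
    lines = []
    for b in boxes:
        x1, y1, x2, y2 = b.corners()  # clip on write
        cx, cy = (x1 + x2) / 2, (y1 + y2) / 2
        w, h = x2 - x1, y2 - y1
        lines.append(f"{b.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def class_stats(manifest: Manifest) -> ClassDistribution:
    counts: dict[int, int] = {c: 0 for c in range(NUM_CLASSES)}
    for _, class_id, _ in manifest.records:
        counts[class_id] += 1
    return ClassDistribution(counts)


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion n items over ratios, exact when n is divisible."""
    raw = [n * r for r in ratios]
    base = [math.floor(v) for v in raw]
    short = n - sum(base)
    order = sorted(range(len(ratios)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:short]:
        base[i] += 1
    return base


def stratified_split(manifest: Manifest, ratios: SplitRatios = SplitRatios(), seed: int = 0) -> Manifest:
    """Assign train/val/test per class with largest-remainder rounding.

    Shuffling within each class is deterministic under ``seed``; every record
    receives exactly one split.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for idx, (_, class_id, _) in enumerate(manifest.records):
        by_class.setdefault(class_id, []).append(idx)

    assignment = [""] * len(manifest.records)
    for class_id in sorted(by_class):
        idxs = np.array(by_class[class_id])
        rng.shuffle(idxs)
        n_train, n_val, n_test = _largest_remainder(len(idxs), ratios.as_tuple())
        for i in idxs[:n_train]:
            assignment[i] = "train"
        for i in idxs[n_train:n_train + n_val]:
            assignment[i] = "val"
        for i in idxs[n_train + n_val:]:
            assignment[i] = "test"

    return Manifest([
        (path, class_id, assignment[i])
        for i, (path, class_id, _) in enumerate(manifest.records)
    ])


def write_dataset_yaml(root: str | Path, manifest: Manifest, out: str | Path) -> None:
    """Emit a detector-tooling compatible dataset description."""
    payload = {
        "path": str(root),
        "train": sorted(p for p, _, s in manifest.records if s == "train"),
        "val": sorted(p for p, _, s in manifest.records if s == "val"),
        "test": sorted(p for p, _, s in manifest.records if s == "test"),
        "nc": NUM_CLASSES,
        "names": list(CLASS_NAMES),
    }
    with open(out, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
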