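"""Deterministic synthetic orchard imagery with five plum defect classes.

Renders stylized plum fruits (shaded ellipses) on leafy or plain backgrounds
and overlays one class-specific defect signature per image:

* diseased     -- irregular dark blotch, annotated as the whole fruit
* insect       -- tiny dark disc holes (small-object regime), per-hole boxes
* bird_pecked  -- wedge notch at the fruit rim, notch-local box
* cracked      -- thin dark polyline across the fruit, crack-local box
* normal       -- no defect, whole-fruit boxes

Geometry is stylized on purpose: the generator exists to exercise the data
pipeline and detector, not to model fruit biology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import BBox, ClassDistribution, Manifest, NUM_CLASSES, write_labels

DISEASED, INSECT, BIRD_PECKED, CRACKED, NORMAL = range(5)


@dataclass(frozen=True)
class DefectShapeParams:
    """Pixel-scale knobs for the defect overlays."""

    hole_radius_px: tuple[int, int] = (2, 6)
    notch_depth_frac: float = 0.35
    crack_length_frac: float = 0.8
    blotch_area_frac: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.hole_radius_px
        if not (1 <= lo <= hi):
            raise ValueError("hole_radius_px must be a non-empty positive range")
        for name in ("notch_depth_frac", "crack_length_frac", "blotch_area_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class SceneSpec:
    image_size: int = 416
    n_fruits: tuple[int, int] = (1, 3)
    defect_class: int = NORMAL
    background_style: str = "leafy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.n_fruits[0] < 1 or self.n_fruits[0] > self.n_fruits[1]:
            raise ValueError("n_fruits must be a range with low >= 1")
        if not 0 <= self.defect_class < NUM_CLASSES:
            raise ValueError(f"invalid defect class id {self.defect_class}")
        if self.background_style not in ("leafy", "plain"):
            raise ValueError(f"unknown background style {self.background_style!r}")


@dataclass
class LabeledImage:
    pixels: np.ndarray  # H x W x 3, uint8
    boxes: list[BBox] = field(default_factory=list)
    class_tag: int = NORMAL


def _background(size: int, style: str, rng: np.random.Generator) -> np.ndarray:
    img = np.empty((size, size, 3), dtype=np.float32)
    base = np.array([96, 124, 68], dtype=np.float32)  # muted foliage green
    img[:] = base
    if style == "leafy":
        # low-frequency blotches stand in for out-of-focus leaves
        for _ in range(24):
            cy, cx = rng.integers(0, size, 2)
            r = int(rng.integers(size // 12, size // 5))
            shade = rng.uniform(-28, 28, 3).astype(np.float32)
            yy, xx = np.ogrid[:size, :size]
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            img[mask] += shade
    img += rng.normal(0, 3.0, img.shape).astype(np.float32)
    return np.clip(img, 0, 255)


def _draw_fruit(img: np.ndarray, cy: float, cx: float, ry: float, rx: float,
                rng: np.random.Generator) -> np.ndarray:
    size = img.shape[0]
    yy, xx = np.ogrid[:size, :size]
    d2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    mask = d2 <= 1.0
    base = np.array([
        rng.uniform(150, 200),  # plum skin: red-purple
        rng.uniform(40, 80),
        rng.uniform(60, 110),
    ], dtype=np.float32)
    shading = np.clip(1.15 - 0.45 * d2, 0.0, 1.2)
    for c in range(3):
        chan = img[:, :, c]
        chan[mask] = base[c] * shading[mask]
    # specular highlight
    hy, hx = cy - 0.4 * ry, cx - 0.4 * rx
    hmask = ((yy - hy) / (0.25 * ry)) ** 2 + ((xx - hx) / (0.25 * rx)) ** 2 <= 1.0
    img[hmask & mask] = np.minimum(img[hmask & mask] + 60, 255)
    return mask


def _disc(img: np.ndarray, cy: int, cx: int, r: int, color) -> None:
    size = img.shape[0]
    yy, xx = np.ogrid[:size, :size]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    img[mask] = color


def _polyline(img: np.ndarray, pts: list[tuple[float, float]], width: int, color) -> tuple[int, int, int, int]:
    """Draw a polyline; return its integer bounding box (y1, x1, y2, x2)."""
    size = img.shape[0]
    ys, xs = [], []
    for (y0, x0), (y1, x1) in zip(pts, pts[1:]):
        n = max(2, int(math.hypot(y1 - y0, x1 - x0)) * 2)
        for t in np.linspace(0, 1, n):
            y, x = y0 + t * (y1 - y0), x0 + t * (x1 - x0)
            yi, xi = int(round(y)), int(round(x))
            lo = -(width // 2)
            hi = lo + width
            for dy in range(lo, hi):
                for dx in range(lo, hi):
                    py, px = yi + dy, xi + dx
                    if 0 <= py < size and 0 <= px < size:
                        img[py, px] = color
                        ys.append(py)
                        xs.append(px)
    return min(ys), min(xs), max(ys), max(xs)


def render_scene(spec: SceneSpec, shapes: DefectShapeParams = DefectShapeParams()) -> LabeledImage:
    """Render one image for ``spec.defect_class`` with tight YOLO boxes.

    The same spec always produces byte-identical pixels and labels.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    img = _background(size, spec.background_style, rng)

    n_fruits = int(rng.integers(spec.n_fruits[0], spec.n_fruits[1] + 1))
    boxes: list[BBox] = []
    placed: list[tuple[float, float, float, float]] = []

    for _ in range(n_fruits):
        r_base = rng.uniform(0.10, 0.16) * size
        ry, rx = r_base * rng.uniform(0.9, 1.1), r_base * rng.uniform(0.9, 1.1)
        for _attempt in range(20):
            cy = rng.uniform(ry + 2, size - ry - 2)
            cx = rng.uniform(rx + 2, size - rx - 2)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (ry + pr) ** 2 for py, px, pr, _ in placed):
                break
        _draw_fruit(img, cy, cx, ry, rx, rng)
        placed.append((cy, cx, max(ry, rx), min(ry, rx)))

        fruit_box = BBox.from_corners(
            spec.defect_class if spec.defect_class in (DISEASED, NORMAL) else NORMAL,
            (cx - rx) / size, (cy - ry) / size, (cx + rx) / size, (cy + ry) / size,
        )

        cls = spec.defect_class
        if cls == NORMAL:
            boxes.append(fruit_box)
        elif cls == DISEASED:
            # irregular blotch: union of random dark discs inside the fruit
            area = shapes.blotch_area_frac * math.pi * ry * rx
            r_blotch = math.sqrt(area / math.pi)
            by = cy + rng.uniform(-0.3, 0.3) * ry
            bx = cx + rng.uniform(-0.3, 0.3) * rx
            for _ in range(6):
                _disc(img, int(by + rng.uniform(-0.5, 0.5) * r_blotch),
                      int(bx + rng.uniform(-0.5, 0.5) * r_blotch),
                      max(2, int(r_blotch * rng.uniform(0.4, 0.7))), (74, 44, 30))
            boxes.append(BBox.from_corners(DISEASED, *fruit_box.corners()))
        elif cls == INSECT:
            n_holes = int(rng.integers(1, 4))
            for _ in range(n_holes):
                r = int(rng.integers(shapes.hole_radius_px[0], shapes.hole_radius_px[1] + 1))
                ang = rng.uniform(0, 2 * math.pi)
                rad = rng.uniform(0, 0.6)
                hy = int(cy + rad * ry * math.sin(ang))
                hx = int(cx + rad * rx * math.cos(ang))
                _disc(img, hy, hx, r, (25, 15, 10))
                pad = 1
                boxes.append(BBox.from_corners(
                    INSECT,
                    (hx - r - pad) / size, (hy - r - pad) / size,
                    (hx + r + pad) / size, (hy + r + pad) / size,
                ))
        elif cls == BIRD_PECKED:
            # wedge notch cut into the rim
            ang = rng.uniform(0, 2 * math.pi)
            depth = shapes.notch_depth_frac * min(ry, rx)
            ny = cy + (ry - depth / 2) * math.sin(ang)
            nx = cx + (rx - depth / 2) * math.cos(ang)
            _disc(img, int(ny), int(nx), max(2, int(depth)), (60, 48, 40))
            d = depth
            boxes.append(BBox.from_corners(
                BIRD_PECKED,
                (nx - d) / size, (ny - d) / size, (nx + d) / size, (ny + d) / size,
            ))
        elif cls == CRACKED:
            length = shapes.crack_length_frac * 2 * min(ry, rx)
            ang = rng.uniform(0, math.pi)
            pts = []
            n_seg = 5
            for i in range(n_seg + 1):
                t = i / n_seg - 0.5
                jitter = rng.uniform(-0.06, 0.06) * length
                pts.append((
                    cy + t * length * math.sin(ang) + jitter * math.cos(ang),
                    cx + t * length * math.cos(ang) - jitter * math.sin(ang),
                ))
            y1, x1, y2, x2 = _polyline(img, pts, 2, (50, 30, 25))
            boxes.append(BBox.from_corners(
                CRACKED, (x1 - 1) / size, (y1 - 1) / size, (x2 + 2) / size, (y2 + 2) / size,
            ))

    pixels = np.clip(img, 0, 255).astype(np.uint8)
    return LabeledImage(pixels=pixels, boxes=boxes, class_tag=spec.defect_class)


def generate_corpus(class_counts: ClassDistribution | dict[int, int],
                    out_dir: str | Path,
                    image_size: int = 416,
                    seed: int = 0,
                    background_style: str = "leafy") -> Manifest:
    """Write ``images/*.png`` + ``labels/*.txt`` + ``manifest.csv``.

    Per-class record counts equal the requested counts; byte-identical output
    for identical (counts, seed).
    """
    counts = class_counts.counts if isinstance(class_counts, ClassDistribution) else dict(class_counts)
    for c, n in counts.items():
        if not 0 <= c < NUM_CLASSES:
            raise ValueError(f"invalid class id {c}")
        if n < 0:
            raise ValueError(f"negative count for class {c}")

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)

    records = []
    for class_id in sorted(counts):
        for i in range(counts[class_id]):
            stem = f"c{class_id}_{i:05d}"
            spec = SceneSpec(image_size=image_size, defect_class=class_id,
                             background_style=background_style,
                             seed=(seed * 1_000_003 + class_id * 100_000 + i) & 0x7FFFFFFF)
            scene = render_scene(spec)
            Image.fromarray(scene.pixels).save(out / "images" / f"{stem}.png")
            write_labels(scene.boxes, out / "labels" / f"{stem}.txt")
            records.append((f"images/{stem}.png", class_id, "unassigned"))

    manifest = Manifest(records)
    manifest.to_csv(out / "manifest.csv")
    return manifest
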