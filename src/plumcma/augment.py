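"""Multi-weather photometric simulation and class-balancing augmentation.

Implements four weather profiles (sunny / rainy / foggy / night), each a
fixed-order composition of photometric ops with parameters sampled uniformly
from configured ranges:

    brightness -> contrast -> saturation -> blur -> rain or fog overlay -> noise

All transforms are photometric or overlay-based: object geometry, and hence
every bounding box, is untouched, so augmented images reuse their source
label file verbatim.
"""

from __future__ import annotations

import json
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import ClassDistribution, Manifest, class_stats

WEATHER_TYPES = ("sunny", "rainy", "foggy", "night")


@dataclass(frozen=True)
class WeatherParams:
    """Parameter ranges for one weather type; ``None`` marks an unused effect."""

    weather: str
    brightness_range: tuple[float, float] | None = None
    contrast_range: tuple[float, float] | None = None
    saturation_range: tuple[float, float] | None = None
    blur_sigma_range: tuple[float, float] | None = None
    rain_count_range: tuple[int, int] | None = None
    rain_length_range: tuple[int, int] | None = None
    rain_width_range: tuple[int, int] | None = None
    fog_color_range: tuple[int, int] | None = None
    fog_intensity_range: tuple[float, float] | None = None
    noise_intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.weather not in WEATHER_TYPES:
            raise ValueError(f"unknown weather {self.weather!r}")
        for name in self.__dataclass_fields__:
            rng = getattr(self, name)
            if name == "weather" or rng is None:
                continue
            if rng[0] > rng[1]:
                raise ValueError(f"{name} is an empty range: {rng}")
        if self.fog_intensity_range is not None:
            lo, hi = self.fog_intensity_range
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError("fog intensity must lie in (0, 1)")


#: the published parameter table: sunny strengthens (>1), the others weaken (<1)
DEFAULT_WEATHER: dict[str, WeatherParams] = {
    "sunny": WeatherParams(
        "sunny",
        brightness_range=(1.1, 1.5),
        contrast_range=(1.1, 1.4),
        saturation_range=(1.1, 1.5),
    ),
    "rainy": WeatherParams(
        "rainy",
        brightness_range=(0.6, 0.9),
        saturation_range=(0.7, 0.9),
        blur_sigma_range=(0.5, 1.5),
        rain_count_range=(30, 100),
        rain_length_range=(10, 25),
        rain_width_range=(1, 2),
    ),
    "foggy": WeatherParams(
        "foggy",
        contrast_range=(0.6, 0.8),
        saturation_range=(0.7, 0.9),
        blur_sigma_range=(0.8, 2.0),
        fog_color_range=(180, 230),
        fog_intensity_range=(0.2, 0.5),
    ),
    "night": WeatherParams(
        "night",
        brightness_range=(0.3, 0.6),
        saturation_range=(0.5, 0.8),
        noise_intensity_range=(5.0, 15.0),
    ),
}


def _check_image(img: np.ndarray) -> None:
    if img.dtype != np.uint8 or img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 uint8 RGB image")


def adjust_brightness(img: np.ndarray, gain: float) -> np.ndarray:
    """Per-pixel multiplicative gain, clipped to [0, 255]."""
    _check_image(img)
    if gain <= 0:
        raise ValueError("gain must be positive")
    out = np.rint(img.astype(np.float64) * gain)
    return np.clip(out, 0, 255).astype(np.uint8)


def adjust_contrast(img: np.ndarray, gain: float) -> np.ndarray:
    """Scale pixel values about the per-image mean (keeps brightness roughly fixed)."""
    _check_image(img)
    if gain <= 0:
        raise ValueError("gain must be positive")
    f = img.astype(np.float64)
    mean = f.mean()
    out = np.rint(mean + (f - mean) * gain)
    return np.clip(out, 0, 255).astype(np.uint8)


def _rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = rgb.max(axis=-1)
    minc = rgb.min(axis=-1)
    v = maxc
    delta = maxc - minc
    s = np.where(maxc > 0, delta / np.maximum(maxc, 1e-12), 0.0)
    # hue in [0, 6)
    with np.errstate(invalid="ignore", divide="ignore"):
        rc = np.where(delta > 0, (maxc - r) / np.maximum(delta, 1e-12), 0.0)
        gc = np.where(delta > 0, (maxc - g) / np.maximum(delta, 1e-12), 0.0)
        bc = np.where(delta > 0, (maxc - b) / np.maximum(delta, 1e-12), 0.0)
    h = np.where(maxc == r, bc - gc, np.where(maxc == g, 2.0 + rc - bc, 4.0 + gc - rc))
    h = np.where(delta > 0, (h / 6.0) % 1.0, 0.0)
    return np.stack([h, s, v], axis=-1)


def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    i = np.floor(h * 6.0)
    f = h * 6.0 - i
    p = v * (1.0 - s)
    q = v * (1.0 - s * f)
    t = v * (1.0 - s * (1.0 - f))
    i = i.astype(np.int64) % 6
    choices = [
        np.stack([v, t, p], -1), np.stack([q, v, p], -1), np.stack([p, v, t], -1),
        np.stack([p, q, v], -1), np.stack([t, p, v], -1), np.stack([v, p, q], -1),
    ]
    out = np.zeros(hsv.shape, dtype=np.float64)
    for k in range(6):
        out[i == k] = choices[k][i == k]
    return out


def adjust_saturation(img: np.ndarray, gain: float) -> np.ndarray:
    """Multiplicative gain on the S channel in HSV space, clipped."""
    _check_image(img)
    if gain <= 0:
        raise ValueError("gain must be positive")
    hsv = _rgb_to_hsv(img.astype(np.float64) / 255.0)
    hsv[..., 1] = np.clip(hsv[..., 1] * gain, 0.0, 1.0)
    out = np.rint(_hsv_to_rgb(hsv) * 255.0)
    return np.clip(out, 0, 255).astype(np.uint8)


def gaussian_kernel1d(sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian with odd size 2*ceil(3*sigma) + 1."""
    radius = int(math.ceil(3.0 * sigma))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur with reflected borders; sigma 0 is the identity."""
    _check_image(img)
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return img.copy()
    k = gaussian_kernel1d(sigma)
    radius = len(k) // 2
    f = img.astype(np.float64)
    padded = np.pad(f, ((radius, radius), (0, 0), (0, 0)), mode="reflect")
    f = np.einsum("k,khwc->hwc", k, np.stack([padded[i:i + img.shape[0]] for i in range(len(k))]))
    padded = np.pad(f, ((0, 0), (radius, radius), (0, 0)), mode="reflect")
    f = np.einsum("k,khwc->hwc", k, np.stack([padded[:, i:i + img.shape[1]] for i in range(len(k))]))
    return np.clip(np.rint(f), 0, 255).astype(np.uint8)


def render_raindrops(img: np.ndarray, count: int, length_px: int, width_px: int,
                     seed: int = 0) -> np.ndarray:
    """Overlay semi-transparent light streaks at a shared near-vertical angle."""
    _check_image(img)
    if count < 0:
        raise ValueError("count must be non-negative")
    if count == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    h, w = img.shape[:2]
    out = img.astype(np.float64)
    angle = math.radians(rng.uniform(70.0, 110.0))  # one angle per image
    dy, dx = math.sin(angle), math.cos(angle)
    streak = np.array([200.0, 200.0, 210.0])
    alpha = 0.55
    for _ in range(count):
        y0 = rng.uniform(0, h)
        x0 = rng.uniform(0, w)
        for t in range(length_px):
            yi = int(round(y0 + t * dy))
            xi = int(round(x0 + t * dx))
            for off in range(width_px):
                xj = xi + off
                if 0 <= yi < h and 0 <= xj < w:
                    out[yi, xj] = (1 - alpha) * out[yi, xj] + alpha * streak
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def blend_fog(img: np.ndarray, fog_color: int, intensity: float) -> np.ndarray:
    """out = (1 - intensity) * img + intensity * fog_color (achromatic fog)."""
    _check_image(img)
    if not 0.0 <= intensity <= 1.0:
        raise ValueError("fog intensity must lie in [0, 1]")
    out = (1.0 - intensity) * img.astype(np.float64) + intensity * float(fog_color)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def add_noise(img: np.ndarray, intensity: float, seed: int = 0) -> np.ndarray:
    """Additive zero-mean Gaussian noise with std = intensity, clipped."""
    _check_image(img)
    if intensity < 0:
        raise ValueError("noise intensity must be non-negative")
    if intensity == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, intensity, img.shape)
    return np.clip(np.rint(img.astype(np.float64) + noise), 0, 255).astype(np.uint8)


def apply_weather(img: np.ndarray, weather: str, rng_seed: int,
                  params: dict[str, WeatherParams] | None = None) -> tuple[np.ndarray, dict]:
    """Sample one parameter set for ``weather`` and apply the op pipeline.

    Returns the transformed image plus the sampled parameter record so each
    augmented file can carry its provenance. Ops run in the fixed order
    brightness, contrast, saturation, blur, rain/fog, noise, skipping effects
    the weather profile does not use.
    """
    _check_image(img)
    table = params or DEFAULT_WEATHER
    if weather not in table:
        raise ValueError(f"unknown weather {weather!r}; expected one of {WEATHER_TYPES}")
    wp = table[weather]
    rng = np.random.default_rng(rng_seed)
    sampled: dict[str, float | int] = {"weather": weather}
    out = img

    if wp.brightness_range:
        g = float(rng.uniform(*wp.brightness_range))
        sampled["brightness"] = g
        out = adjust_brightness(out, g)
    if wp.contrast_range:
        g = float(rng.uniform(*wp.contrast_range))
        sampled["contrast"] = g
        out = adjust_contrast(out, g)
    if wp.saturation_range:
        g = float(rng.uniform(*wp.saturation_range))
        sampled["saturation"] = g
        out = adjust_saturation(out, g)
    if wp.blur_sigma_range:
        s = float(rng.uniform(*wp.blur_sigma_range))
        sampled["blur_sigma"] = s
        out = gaussian_blur(out, s)
    if wp.rain_count_range:
        count = int(rng.integers(wp.rain_count_range[0], wp.rain_count_range[1] + 1))
        length = int(rng.integers(wp.rain_length_range[0], wp.rain_length_range[1] + 1))
        width = int(rng.integers(wp.rain_width_range[0], wp.rain_width_range[1] + 1))
        sampled.update(rain_count=count, rain_length=length, rain_width=width)
        out = render_raindrops(out, count, length, width, seed=int(rng.integers(0, 2**31)))
    if wp.fog_color_range:
        color = int(rng.integers(wp.fog_color_range[0], wp.fog_color_range[1] + 1))
        intensity = float(rng.uniform(*wp.fog_intensity_range))
        sampled.update(fog_color=color, fog_intensity=intensity)
        out = blend_fog(out, color, intensity)
    if wp.noise_intensity_range:
        intensity = float(rng.uniform(*wp.noise_intensity_range))
        sampled["noise_intensity"] = intensity
        out = add_noise(out, intensity, seed=int(rng.integers(0, 2**31)))

    if out is img:
        out = img.copy()
    return out, sampled


@dataclass
class AugmentationPlan:
    """Per-class top-up schedule: which sources get which weather, fully seeded."""

    target_per_class: int
    per_class_new: dict[int, int]
    assignments: list[tuple[str, int, str, int]] = field(default_factory=list)
    # each assignment: (source path, class id, weather, per-image seed)


def plan_balance(manifest: Manifest, target_per_class: int = 2000,
                 seed: int = 0, classes=None) -> AugmentationPlan:
    """Schedule max(0, target - count) new images per class.

    Sources are drawn uniformly with replacement from the class's originals and
    weather types uniformly over the four profiles. A class that already meets
    the target contributes nothing; a requested class with a deficit but no
    originals is an error. ``classes`` defaults to the classes present in the
    manifest.
    """
    if target_per_class < 0:
        raise ValueError("target must be non-negative")
    dist = class_stats(manifest)
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[str]] = {}
    for path, class_id, _ in manifest.records:
        by_class.setdefault(class_id, []).append(path)
    if classes is None:
        classes = sorted(by_class)

    per_class_new: dict[int, int] = {}
    assignments: list[tuple[str, int, str, int]] = []
    for class_id in sorted(classes):
        count = dist[class_id]
        deficit = max(0, target_per_class - count)
        per_class_new[class_id] = deficit
        if deficit == 0:
            continue
        if count == 0:
            raise ValueError(f"class {class_id} has no originals to augment from")
        sources = by_class[class_id]
        for _ in range(deficit):
            src = sources[int(rng.integers(0, len(sources)))]
            weather = WEATHER_TYPES[int(rng.integers(0, len(WEATHER_TYPES)))]
            assignments.append((src, class_id, weather, int(rng.integers(0, 2**31))))
    return AugmentationPlan(target_per_class, per_class_new, assignments)


def execute_plan(plan: AugmentationPlan, manifest: Manifest, root: str | Path,
                 out_dir: str | Path,
                 params: dict[str, WeatherParams] | None = None) -> Manifest:
    """Render every planned augmentation and merge into a balanced manifest.

    Augmented images copy their source label file unchanged (photometric ops
    preserve geometry) and record the sampled weather parameters as a JSON
    sidecar.
    """
    root = Path(root)
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)

    records = list(manifest.records)
    for i, (src, class_id, weather, img_seed) in enumerate(plan.assignments):
        src_path = root / src
        if not src_path.exists():
            raise FileNotFoundError(f"missing source image {src_path}")
        img = np.asarray(Image.open(src_path).convert("RGB"))
        aug, sampled = apply_weather(img, weather, img_seed, params=params)
        stem = f"aug_{weather}_{i:05d}"
        Image.fromarray(aug).save(out / "images" / f"{stem}.png")
        src_label = root / "labels" / (Path(src).stem + ".txt")
        shutil.copyfile(src_label, out / "labels" / f"{stem}.txt")
        sampled["source"] = str(src)
        (out / "images" / f"{stem}.json").write_text(json.dumps(sampled, sort_keys=True))
        records.append((f"images/{stem}.png", class_id, "unassigned"))

    merged = Manifest(records)
    merged.to_csv(out / "manifest.csv")
    return merged
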