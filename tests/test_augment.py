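import hashlib
from pathlib import Path

import numpy as np
import pytest

from plumcma.augment import (DEFAULT_WEATHER, add_noise, adjust_brightness,
                             adjust_contrast, adjust_saturation, apply_weather,
                             blend_fog, execute_plan, gaussian_blur,
                             gaussian_kernel1d, plan_balance, render_raindrops)
from plumcma.data import class_stats
from .conftest import synthetic_manifest


@pytest.fixture()
def img(rng):
    return rng.integers(0, 256, (48, 48, 3), dtype=np.uint8)


class TestPhotometricOps:
    def test_identity_gains(self, img):
        assert np.array_equal(adjust_brightness(img, 1.0), img)
        assert np.array_equal(adjust_contrast(img, 1.0), img)
        assert np.array_equal(adjust_saturation(img, 1.0), img)

    def test_brightness_clipping_bound(self):
        px = np.full((4, 4, 3), 200, np.uint8)
        assert (adjust_brightness(px, 1.5) == 255).all()

    def test_brightness_forced_arithmetic(self):
        px = np.full((4, 4, 3), 100, np.uint8)
        assert (adjust_brightness(px, 0.3) == 30).all()

    def test_nonpositive_gain_rejected(self, img):
        for op in (adjust_brightness, adjust_contrast, adjust_saturation):
            with pytest.raises(ValueError):
                op(img, 0.0)

    def test_contrast_pivots_on_mean(self):
        px = np.zeros((2, 2, 3), np.uint8)
        px[0] = 100
        px[1] = 200  # mean = 150
        out = adjust_contrast(px, 2.0)
        assert (out[0] == 50).all() and (out[1] == 250).all()

    def test_saturation_desaturates_to_gray(self, img):
        out = adjust_saturation(img, 1e-6)
        # near-zero saturation: channels equal (value channel preserved)
        assert (np.abs(out.astype(int).max(-1) - out.astype(int).min(-1)) <= 1).all()

    def test_shapes_and_dtype_preserved(self, img):
        for out in (adjust_brightness(img, 1.3), adjust_contrast(img, 0.7),
                    adjust_saturation(img, 1.2), gaussian_blur(img, 1.0),
                    blend_fog(img, 200, 0.3), add_noise(img, 10, 0),
                    render_raindrops(img, 10, 12, 1, 0)):
            assert out.shape == img.shape and out.dtype == np.uint8


class TestGaussianBlur:
    def test_sigma_zero_identity(self, img):
        assert np.array_equal(gaussian_blur(img, 0.0), img)

    def test_constant_image_invariant(self):
        px = np.full((32, 32, 3), 77, np.uint8)
        assert np.array_equal(gaussian_blur(px, 1.3), px)

    def test_kernel_size_is_2ceil3sigma_plus_1(self):
        assert len(gaussian_kernel1d(1.0)) == 7
        assert len(gaussian_kernel1d(1.4)) == 2 * 5 + 1

    def test_impulse_center_equals_kernel_center_weight(self):
        # independent oracle: explicit normalized kernel evaluation
        sigma = 1.0
        k = gaussian_kernel1d(sigma)
        center_weight = k[len(k) // 2] ** 2  # separable: product of two 1-D centers
        px = np.zeros((31, 31, 3), np.uint8)
        px[15, 15] = 255
        out = gaussian_blur(px, sigma)
        assert out[15, 15, 0] == int(round(255 * center_weight))


class TestRaindrops:
    def test_count_zero_identity(self, img):
        assert np.array_equal(render_raindrops(img, 0, 10, 1, 0), img)

    def test_streaks_on_black_image(self):
        black = np.zeros((96, 96, 3), np.uint8)
        out = render_raindrops(black, 50, 12, 1, seed=4)
        assert (out > 0).any()
        # count connected streak components (8-connectivity), must be <= 50
        mask = out[:, :, 0] > 0
        seen = np.zeros_like(mask)
        comps = 0
        for i in range(96):
            for j in range(96):
                if mask[i, j] and not seen[i, j]:
                    comps += 1
                    stack = [(i, j)]
                    while stack:
                        y, x = stack.pop()
                        if 0 <= y < 96 and 0 <= x < 96 and mask[y, x] and not seen[y, x]:
                            seen[y, x] = True
                            stack += [(y + dy, x + dx)
                                      for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                                      if (dy, dx) != (0, 0)]
        assert 0 < comps <= 50

    def test_seed_determinism(self, img):
        a = render_raindrops(img, 30, 15, 2, seed=7)
        b = render_raindrops(img, 30, 15, 2, seed=7)
        assert np.array_equal(a, b)


class TestFogNoise:
    def test_fog_intensity_zero_identity(self, img):
        assert np.array_equal(blend_fog(img, 200, 0.0), img)

    def test_fog_intensity_one_uniform(self, img):
        assert (blend_fog(img, 213, 1.0) == 213).all()

    def test_fog_forced_arithmetic(self):
        px = np.full((3, 3, 3), 100, np.uint8)
        assert (blend_fog(px, 200, 0.5) == 150).all()

    def test_noise_zero_identity(self, img):
        assert np.array_equal(add_noise(img, 0, 0), img)

    def test_noise_std_matches_intensity(self):
        px = np.full((200, 200, 3), 128, np.uint8)
        out = add_noise(px, 10.0, seed=1)
        std = (out.astype(float) - 128).std()
        assert abs(std - 10.0) / 10.0 < 0.05

    def test_noise_determinism(self, img):
        assert np.array_equal(add_noise(img, 8, 3), add_noise(img, 8, 3))


class TestApplyWeather:
    def test_sunny_samples_within_ranges_and_skips_others(self, img):
        out, sampled = apply_weather(img, "sunny", 5)
        assert 1.1 <= sampled["brightness"] <= 1.5
        assert 1.1 <= sampled["contrast"] <= 1.4
        assert 1.1 <= sampled["saturation"] <= 1.5
        for k in ("blur_sigma", "rain_count", "fog_color", "noise_intensity"):
            assert k not in sampled

    def test_night_profile(self, img):
        out, sampled = apply_weather(img, "night", 6)
        assert 0.3 <= sampled["brightness"] <= 0.6
        assert 0.5 <= sampled["saturation"] <= 0.8
        assert 5 <= sampled["noise_intensity"] <= 15
        assert "contrast" not in sampled and "blur_sigma" not in sampled

    def test_rainy_and_foggy_profiles(self, img):
        _, rain = apply_weather(img, "rainy", 1)
        assert 30 <= rain["rain_count"] <= 100
        assert 10 <= rain["rain_length"] <= 25
        assert 1 <= rain["rain_width"] <= 2
        _, fog = apply_weather(img, "foggy", 2)
        assert 180 <= fog["fog_color"] <= 230
        assert 0.2 <= fog["fog_intensity"] <= 0.5

    def test_seed_determinism(self, img):
        a, pa = apply_weather(img, "foggy", 11)
        b, pb = apply_weather(img, "foggy", 11)
        assert np.array_equal(a, b) and pa == pb

    def test_sunny_never_darkens_night_never_brightens(self, rng):
        mid = rng.integers(60, 180, (32, 32, 3), dtype=np.uint8)  # non-saturated
        for seed in range(3):
            sunny, _ = apply_weather(mid, "sunny", seed)
            night, _ = apply_weather(mid, "night", seed)
            assert sunny.mean() >= mid.mean()
            assert night.mean() <= mid.mean()

    def test_unknown_weather_rejected(self, img):
        with pytest.raises(ValueError):
            apply_weather(img, "hail", 0)


class TestPlanBalance:
    def test_deficit_arithmetic(self):
        m = synthetic_manifest({1: 788})
        plan = plan_balance(m, 2000, seed=0)
        assert plan.per_class_new[1] == 1212

    def test_paper_distribution_arithmetic(self, paper_distribution):
        m = synthetic_manifest(paper_distribution.counts)
        plan = plan_balance(m, 2000, seed=0)
        assert sum(plan.per_class_new.values()) == 4085
        assert len(plan.assignments) == 4085
        final = {c: paper_distribution[c] + plan.per_class_new[c] for c in range(5)}
        assert final == {c: 2000 for c in range(5)}
        assert sum(final.values()) == 10000

    def test_class_at_target_untouched(self):
        m = synthetic_manifest({0: 10, 1: 5})
        plan = plan_balance(m, 10, seed=0)
        assert plan.per_class_new[0] == 0
        assert plan.per_class_new[1] == 5

    def test_balanced_fixed_point(self):
        m = synthetic_manifest({c: 7 for c in range(5)})
        plan = plan_balance(m, 7, seed=0)
        assert not plan.assignments

    def test_zero_originals_with_deficit_errors(self):
        bad = synthetic_manifest({3: 2})  # classes 0/1/2/4 empty
        with pytest.raises(ValueError, match="no originals"):
            plan_balance(bad, 5, classes=range(5))
        # the same manifest is fine when only present classes are requested
        assert plan_balance(bad, 5).per_class_new == {3: 3}

    def test_weather_assignment_uniform_coverage(self, paper_distribution):
        m = synthetic_manifest(paper_distribution.counts)
        plan = plan_balance(m, 2000, seed=1)
        weathers = {w for _, _, w, _ in plan.assignments}
        assert weathers == {"sunny", "rainy", "foggy", "night"}


class TestExecutePlan:
    def test_execute_reaches_target_and_preserves_labels(self, tiny_corpus, tmp_path):
        root, manifest = tiny_corpus
        plan = plan_balance(manifest, 5, seed=2)
        merged = execute_plan(plan, manifest, root, tmp_path)
        stats = class_stats(merged)
        assert stats.counts == {c: 5 for c in range(5)}
        # every augmented label file byte-equal to its source label file
        for i, (src, _, weather, _) in enumerate(plan.assignments):
            aug_label = tmp_path / "labels" / f"aug_{weather}_{i:05d}.txt"
            src_label = root / "labels" / (Path(src).stem + ".txt")
            assert aug_label.read_bytes() == src_label.read_bytes()

    def test_execute_determinism(self, tiny_corpus, tmp_path):
        root, manifest = tiny_corpus
        plan = plan_balance(manifest, 4, seed=5)
        outs = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            execute_plan(plan, manifest, root, out)
            outs.append({
                p.name: hashlib.sha256(p.read_bytes()).hexdigest()
                for p in sorted((out / "images").glob("*")) if p.is_file()
            })
        assert outs[0] == outs[1]

    def test_missing_source_errors(self, tiny_corpus, tmp_path):
        root, manifest = tiny_corpus
        plan = plan_balance(manifest, 4, seed=5)
        bad = plan.assignments[0]
        plan.assignments[0] = ("images/ghost.png", bad[1], bad[2], bad[3])
        with pytest.raises(FileNotFoundError):
            execute_plan(plan, manifest, root, tmp_path)
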