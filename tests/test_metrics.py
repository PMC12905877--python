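import numpy as np
import pytest

from plumcma.metrics import (Detection, IOU_SWEEP, average_precision, evaluate,
                             f1, iou, match_detections, precision, recall)

# ---------------------------------------------------------------------------
# Independent brute-force oracle.  Re-implements the protocol from the
# definitions: greedy confidence-ordered matching, explicit PR staircase,
# envelope integration by direct enumeration of every distinct recall level.
# ---------------------------------------------------------------------------


def oracle_iou(a, b):
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area = (a[2] - a[0]) * (a[3] - a[1]) + (b[2] - b[0]) * (b[3] - b[1]) - inter
    return inter / area if area > 0 else 0.0


def oracle_ap_for_class(dets, truths, thr):
    """dets: list of (image, box, conf); truths: list of (image, box)."""
    # greedy matching per image
    records = []  # (conf, is_tp)
    total_truths = len(truths)
    images = {img for img, _ in truths} | {img for img, _, _ in dets}
    for img in images:
        img_dets = sorted([d for d in dets if d[0] == img], key=lambda d: -d[2])
        img_truths = [t[1] for t in truths if t[0] == img]
        used = set()
        for _, box, conf in img_dets:
            cands = [(oracle_iou(box, t), j) for j, t in enumerate(img_truths) if j not in used]
            cands = [c for c in cands if c[0] >= thr]
            if cands:
                best = max(cands)
                used.add(best[1])
                records.append((conf, True))
            else:
                records.append((conf, False))
    if total_truths == 0:
        return 0.0
    records.sort(key=lambda r: -r[0])
    # explicit PR staircase
    pr = []
    tp = fp = 0
    for _, is_tp in records:
        tp += is_tp
        fp += not is_tp
        pr.append((tp / total_truths, tp / (tp + fp)))
    # envelope integration over every distinct recall level
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(pr):
        if r > prev_r:
            p_env = max(p for rr, p in pr if rr >= r)
            ap += (r - prev_r) * p_env
            prev_r = r
    return ap


def oracle_evaluate(dets, truths, classes):
    """Exhaustive per-class, per-threshold evaluation."""
    ap50, ap5095 = {}, {}
    for c in classes:
        cd = [(d.image_id, d.box, d.confidence) for d in dets if d.class_id == c]
        ct = [(img, box) for img, cc, box in truths if cc == c]
        aps = [oracle_ap_for_class(cd, ct, t) for t in IOU_SWEEP]
        ap50[c] = aps[0]
        ap5095[c] = float(np.mean(aps))
    n = len(classes)
    return sum(ap50.values()) / n, sum(ap5095.values()) / n, ap50


# ---------------------------------------------------------------------------


class TestIoU:
    def test_identical(self):
        assert iou((0, 0, 1, 1), (0, 0, 1, 1)) == 1.0

    def test_disjoint(self):
        assert iou((0, 0, 1, 1), (2, 2, 3, 3)) == 0.0

    def test_hand_computed_overlap(self):
        # areas: 4 and 4, intersection 1, union 7
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)


class TestMatching:
    def test_single_tp(self):
        res = match_detections([((0, 0, 1, 1), 0.9)], [(0.1, 0.1, 1, 1)], 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_double_detection_one_tp_one_fp(self):
        truth = [(0, 0, 1, 1)]
        dets = [((0, 0, 1, 1), 0.9), ((0, 0, 1, 1), 0.8)]
        res = match_detections(dets, truth, 0.5)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_no_detections_all_fn(self):
        res = match_detections([], [(0, 0, 1, 1), (0, 0, 0.5, 0.5)], 0.5)
        assert (res.tp, res.fp, res.fn) == (0, 0, 2)

    def test_tp_bounded_by_truths(self):
        truths = [(0, 0, 1, 1)]
        dets = [((0, 0, 1, 1), c) for c in (0.9, 0.8, 0.7)]
        assert match_detections(dets, truths, 0.5).tp <= 1


class TestScalarMetrics:
    def test_precision(self):
        assert precision(8, 2) == pytest.approx(0.8)

    def test_recall(self):
        assert recall(8, 8) == pytest.approx(0.5)

    def test_f1_guarded(self):
        assert f1(0.0, 0.0) == 0.0

    def test_empty_denominators(self):
        assert precision(0, 0) == 0.0
        assert recall(0, 0) == 0.0


class TestAveragePrecision:
    def test_tp_then_fp_is_one(self):
        assert average_precision([True, False], 1) == pytest.approx(1.0)

    def test_fp_then_tp_is_half(self):
        assert average_precision([False, True], 1) == pytest.approx(0.5)

    def test_perfect_ranking(self):
        assert average_precision([True] * 4, 4) == pytest.approx(1.0)

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 8))
            flags = rng.random(n) > 0.5
            nt = int(rng.integers(max(1, flags.sum()), flags.sum() + 4))
            assert 0.0 <= average_precision(list(flags), nt) <= 1.0


def _random_instance(rng, max_dets=10):
    classes = [0, 1]
    truths, dets = [], []
    for img in ("a", "b"):
        for _ in range(int(rng.integers(0, 4))):
            x, y = rng.uniform(0, 0.6, 2)
            w, h = rng.uniform(0.1, 0.4, 2)
            truths.append((img, int(rng.integers(0, 2)), (x, y, x + w, y + h)))
    n_dets = int(rng.integers(0, max_dets + 1))
    for _ in range(n_dets):
        if truths and rng.random() < 0.7:  # perturbed copy of a truth
            img, c, (x1, y1, x2, y2) = truths[int(rng.integers(0, len(truths)))]
            j = rng.uniform(-0.08, 0.08, 4)
            box = (x1 + j[0], y1 + j[1], max(x1 + j[0] + 0.01, x2 + j[2]),
                   max(y1 + j[1] + 0.01, y2 + j[3]))
        else:
            img = ("a", "b")[int(rng.integers(0, 2))]
            c = int(rng.integers(0, 2))
            x, y = rng.uniform(0, 0.6, 2)
            w, h = rng.uniform(0.05, 0.4, 2)
            box = (x, y, x + w, y + h)
        dets.append(Detection(img, c, box, float(rng.uniform(0.05, 1.0))))
    return dets, truths, classes


class TestEvaluate:
    def test_perfect_detections(self):
        truths = [("a", 0, (0.1, 0.1, 0.4, 0.4)), ("a", 1, (0.5, 0.5, 0.9, 0.9))]
        dets = [Detection(img, c, box, 1.0) for img, c, box in truths]
        rep = evaluate(dets, truths, classes=[0, 1])
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 == pytest.approx(1.0)
        assert rep.mean_precision == pytest.approx(1.0)
        assert rep.mean_recall == pytest.approx(1.0)
        assert rep.mean_f1 == pytest.approx(1.0)

    def test_no_detections(self):
        truths = [("a", 0, (0.1, 0.1, 0.4, 0.4))]
        rep = evaluate([], truths, classes=[0])
        assert rep.map50 == 0.0 and rep.mean_precision == 0.0
        assert rep.mean_recall == 0.0 and rep.mean_f1 == 0.0

    def test_map_ordering_invariant(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            dets, truths, classes = _random_instance(rng)
            rep = evaluate(dets, truths, classes=classes)
            assert rep.map50_95 <= rep.map50 + 1e-12

    def test_oracle_equivalence_small_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            dets, truths, classes = _random_instance(rng)
            rep = evaluate(dets, truths, classes=classes)
            o50, o5095, per50 = oracle_evaluate(dets, truths, classes)
            assert rep.map50 == pytest.approx(o50, abs=1e-9)
            assert rep.map50_95 == pytest.approx(o5095, abs=1e-9)
            for c in classes:
                assert rep.per_class[c]["ap50"] == pytest.approx(per50[c], abs=1e-9)

    def test_duplication_invariance(self):
        # duplicating the whole instance into a disjoint second image keeps AP
        truths = [("a", 0, (0.1, 0.1, 0.3, 0.3)), ("a", 0, (0.5, 0.5, 0.8, 0.8))]
        dets = [Detection("a", 0, (0.1, 0.1, 0.3, 0.3), 0.9),
                Detection("a", 0, (0.4, 0.1, 0.6, 0.3), 0.6)]
        rep1 = evaluate(dets, truths, classes=[0])
        truths2 = truths + [("b", c, box) for _, c, box in truths]
        dets2 = dets + [Detection("b", d.class_id, d.box, d.confidence) for d in dets]
        rep2 = evaluate(dets2, truths2, classes=[0])
        assert rep1.map50 == pytest.approx(rep2.map50)

    def test_101_point_close_to_exact(self):
        rng = np.random.default_rng(5)
        dets, truths, classes = _random_instance(rng)
        a = evaluate(dets, truths, classes=classes, interpolation="all")
        b = evaluate(dets, truths, classes=classes, interpolation="101")
        assert abs(a.map50 - b.map50) < 0.05
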