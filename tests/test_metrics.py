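import numpy as np
import pytest
from shapely.geometry import box as shapely_box

from pigpen.frames import Box
from pigpen.metrics import (MatchCounts, average_precision_50, evaluate_images,
                            integrated_performance, iou, match_detections,
                            precision, recall)


def shapely_iou(a: Box, b: Box) -> float:
    """Independent IoU via polygon geometry."""
    pa = shapely_box(a.x_min, a.y_min, a.x_max, a.y_max)
    pb = shapely_box(b.x_min, b.y_min, b.x_max, b.y_max)
    union = pa.union(pb).area
    return pa.intersection(pb).area / union if union else 0.0


def reference_match(preds, truths, thr):
    """Brute-force VOC matcher using the geometric IoU."""
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))
    taken = set()
    tp = 0
    for i in order:
        ious = [(shapely_iou(preds[i], t), j) for j, t in enumerate(truths)
                if j not in taken]
        if not ious:
            continue
        best_iou, best_j = max(ious)
        if best_iou >= thr:
            taken.add(best_j)
            tp += 1
    return MatchCounts(tp=tp, fp=len(preds) - tp, fn=len(truths) - tp)


def reference_ap(all_preds, all_truths, thr=0.5):
    """AP by enumerating every confidence cutoff and re-matching from scratch,
    then taking max precision at recall >= r over the distinct recall levels."""
    n_truth = sum(len(t) for t in all_truths)
    confs = sorted({p.confidence for preds in all_preds for p in preds},
                   reverse=True)
    points = []
    for c in confs:
        tp = fp = 0
        for preds, truths in zip(all_preds, all_truths):
            kept = [p for p in preds if p.confidence >= c]
            m = reference_match(kept, truths, thr)
            tp += m.tp
            fp += m.fp
        points.append((tp / n_truth, tp / (tp + fp) if tp + fp else 0.0))
    ap, prev_r = 0.0, 0.0
    for r in sorted({r for r, _ in points}):
        best_p = max(p for rr, p in points if rr >= r)
        ap += (r - prev_r) * best_p
        prev_r = r
    return 100.0 * ap


def random_boxes(rng, n, w=100, h=100, conf=True):
    out = []
    for _ in range(n):
        x0, y0 = rng.uniform(0, w - 12), rng.uniform(0, h - 12)
        out.append(Box(x0, y0, x0 + rng.uniform(4, 25), y0 + rng.uniform(4, 25),
                       float(rng.uniform(0.05, 1)) if conf else 1.0))
    return out


class TestIou:
    def test_identical_boxes(self):
        assert iou(Box(2, 3, 9, 8), Box(2, 3, 9, 8)) == 1.0

    def test_disjoint_boxes(self):
        assert iou(Box(0, 0, 5, 5), Box(10, 10, 15, 15)) == 0.0

    def test_half_overlap_hand_value(self):
        assert iou(Box(0, 0, 10, 10), Box(5, 0, 15, 10)) == pytest.approx(1 / 3)

    def test_matches_geometric_oracle(self, rng):
        a = random_boxes(rng, 20)
        b = random_boxes(rng, 20)
        for x, y in zip(a, b):
            assert iou(x, y) == pytest.approx(shapely_iou(x, y), abs=1e-9)


class TestMatching:
    def test_perfect_predictions(self, rng):
        truths = random_boxes(rng, 6, conf=False)
        preds = [Box(b.x_min, b.y_min, b.x_max, b.y_max, 0.9) for b in truths]
        m = match_detections(preds, truths)
        assert (m.tp, m.fp, m.fn) == (6, 0, 0)

    def test_no_predictions(self, rng):
        truths = random_boxes(rng, 4, conf=False)
        m = match_detections([], truths)
        assert (m.tp, m.fp, m.fn) == (0, 0, 4)

    def test_matches_brute_force_reference(self, rng):
        for _ in range(20):
            preds = random_boxes(rng, int(rng.integers(0, 15)))
            truths = random_boxes(rng, int(rng.integers(0, 10)), conf=False)
            ours = match_detections(preds, truths)
            ref = reference_match(preds, truths, 0.5)
            assert (ours.tp, ours.fp, ours.fn) == (ref.tp, ref.fp, ref.fn)


class TestPrecisionRecall:
    def test_degenerate_zero_counts(self):
        assert precision(0, 0) == 0
        assert recall(0, 0) == 0

    def test_basic_ratios(self):
        assert precision(3, 1) == pytest.approx(0.75)
        assert recall(3, 2) == pytest.approx(0.6)


class TestAveragePrecision:
    def test_perfect_detector_scores_100(self, rng):
        truths = [random_boxes(rng, 4, conf=False) for _ in range(3)]
        preds = [[Box(b.x_min, b.y_min, b.x_max, b.y_max, rng.uniform(0.1, 1))
                  for b in t] for t in truths]
        assert average_precision_50(preds, truths) == pytest.approx(100.0)

    def test_no_predictions_scores_0(self, rng):
        truths = [random_boxes(rng, 3, conf=False)]
        assert average_precision_50([[]], truths) == 0.0

    def test_no_ground_truth_errors(self):
        with pytest.raises(ValueError):
            average_precision_50([[]], [[]])

    def test_matches_threshold_enumeration_oracle(self, rng):
        for _ in range(20):
            truths, preds = [], []
            for _ in range(5):
                t = random_boxes(rng, int(rng.integers(1, 4)), conf=False)
                p = []
                for b in t:  # noisy copies of some truths + distractors
                    if rng.random() < 0.7:
                        j = rng.uniform(-1.5, 1.5, 4)
                        p.append(Box(b.x_min + j[0], b.y_min + j[1],
                                     b.x_max + j[2], b.y_max + j[3],
                                     float(rng.uniform(0.05, 1))))
                p.extend(random_boxes(rng, int(rng.integers(0, 3))))
                truths.append(t)
                preds.append(p)
            ours = average_precision_50(preds, truths)
            ref = reference_ap(preds, truths)
            assert ours == pytest.approx(ref, abs=1e-6)

    def test_invariant_to_prediction_order(self, rng):
        truths = [random_boxes(rng, 5, conf=False) for _ in range(4)]
        preds = [random_boxes(rng, 8) for _ in range(4)]
        shuffled = [list(p) for p in preds]
        for p in shuffled:
            rng.shuffle(p)
        assert average_precision_50(preds, truths) == pytest.approx(
            average_precision_50(shuffled, truths))


class TestIntegratedPerformance:
    def test_zero_accuracy_gives_zero(self):
        assert integrated_performance(0.0, 36.3) == 0.0

    def test_rounded_to_one_decimal(self):
        assert integrated_performance(50.05, 2.0) == 100.1

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            integrated_performance(-1.0, 2.0)


class TestEvaluateImages:
    def test_oracle_detector_at_zero_rates_is_perfect(self, tiny_scene):
        from pigpen.synthetic import oracle_detector
        _, frames = tiny_scene
        preds = {f"{i:04d}": oracle_detector(t, rng=i) for i, t in enumerate(frames)}
        truths = {f"{i:04d}": t.boxes for i, t in enumerate(frames)}
        rep = evaluate_images(preds, truths)
        assert rep["precision"] == 1.0 and rep["recall"] == 1.0
        assert rep["ap50"] == 100.0
        assert rep["fp"] == 0 and rep["fn"] == 0

    def test_recall_tracks_miss_rate(self, tiny_scene):
        from pigpen.synthetic import oracle_detector
        _, frames = tiny_scene
        rng = np.random.default_rng(8)
        preds, truths = {}, {}
        for rep_i in range(20):  # repeat the scene to accumulate boxes
            for i, t in enumerate(frames):
                key = f"{rep_i}_{i}"
                preds[key] = oracle_detector(t, miss_rate=0.3, rng=rng)
                truths[key] = t.boxes
        rep = evaluate_images(preds, truths)
        n = sum(len(v) for v in truths.values())
        sigma = np.sqrt(0.3 * 0.7 / n)
        assert rep["recall"] == pytest.approx(0.7, abs=3 * sigma + 0.005)
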