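import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pigpen.frames import (Box, box_iou, boxes_mask, nms, read_boxes, read_frame,
                           read_frames, resize_frame, to_grayscale, write_boxes,
                           write_frame)


class TestGrayscale:
    @pytest.mark.parametrize("value", [0, 87, 255])
    def test_equal_planes_are_fixed_points(self, value):
        frame = np.full((4, 5, 3), value, dtype=np.uint8)
        assert np.all(to_grayscale(frame) == value)

    def test_bt601_luma_hand_value(self):
        frame = np.zeros((1, 1, 3), dtype=np.uint8)
        frame[0, 0] = (100, 150, 200)
        # round(0.299*100 + 0.587*150 + 0.114*200) = round(141.25) = 141
        assert to_grayscale(frame)[0, 0] == 141

    def test_gray_input_passthrough(self, rng):
        img = rng.integers(0, 256, (6, 7)).astype(np.uint8)
        assert np.array_equal(to_grayscale(img), img)


class TestResize:
    def test_target_dimensions(self, rng):
        img = rng.integers(0, 256, (1080, 1920)).astype(np.uint8)
        out = resize_frame(img, 512, 288)
        assert out.shape == (288, 512)

    def test_identity_resize(self, rng):
        img = rng.integers(0, 256, (20, 30)).astype(np.uint8)
        assert np.array_equal(resize_frame(img, 30, 20), img)

    def test_constant_frame_stays_constant(self):
        img = np.full((36, 48), 100, dtype=np.uint8)
        assert np.all(resize_frame(img, 17, 11) == 100)

    def test_rejects_nonpositive_dims(self):
        with pytest.raises(ValueError):
            resize_frame(np.zeros((4, 4), np.uint8), 0, 5)


class TestFrameIO:
    def test_directory_read_in_name_order(self, tmp_path, rng):
        frames = [rng.integers(0, 256, (8, 9)).astype(np.uint8) for _ in range(3)]
        for i, f in enumerate(frames):
            write_frame(f, tmp_path / f"{i:03d}.png")
        loaded = list(read_frames(tmp_path, as_gray=True))
        assert len(loaded) == 3
        for a, b in zip(frames, loaded):
            assert np.array_equal(a, b)

    def test_empty_directory_errors(self, tmp_path):
        with pytest.raises(ValueError):
            list(read_frames(tmp_path))

    def test_mixed_dimensions_error(self, tmp_path, rng):
        write_frame(rng.integers(0, 256, (8, 9)).astype(np.uint8), tmp_path / "a.png")
        write_frame(rng.integers(0, 256, (9, 9)).astype(np.uint8), tmp_path / "b.png")
        with pytest.raises(ValueError, match="mixed"):
            list(read_frames(tmp_path))

    def test_png_round_trip_lossless(self, tmp_path, rng):
        img = rng.integers(0, 256, (16, 24)).astype(np.uint8)
        write_frame(img, tmp_path / "x.png")
        assert np.array_equal(read_frame(tmp_path / "x.png", as_gray=True), img)


class TestBoxIO:
    def test_full_frame_box(self, tmp_path):
        (tmp_path / "b.txt").write_text("0 0.5 0.5 1.0 1.0\n")
        (box,) = read_boxes(tmp_path / "b.txt", 512, 288)
        assert (box.x_min, box.y_min, box.x_max, box.y_max) == (0, 0, 512, 288)

    def test_empty_file_gives_empty_list(self, tmp_path):
        (tmp_path / "b.txt").write_text("")
        assert read_boxes(tmp_path / "b.txt", 100, 100) == []

    def test_round_trip_is_idempotent_at_text_level(self, tmp_path, rng):
        w, h = 640, 480
        boxes = []
        for _ in range(100):
            x0, y0 = rng.uniform(0, w - 10), rng.uniform(0, h - 10)
            boxes.append(Box(x0, y0, x0 + rng.uniform(1, w - x0),
                             y0 + rng.uniform(1, h - y0), rng.uniform(0.01, 1)))
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        write_boxes(boxes, p1, w, h)
        write_boxes(read_boxes(p1, w, h), p2, w, h)
        assert p1.read_text() == p2.read_text()

    def test_round_trip_preserves_boxes_to_half_pixel(self, tmp_path, rng):
        w, h = 512, 288
        boxes = [Box(10.25, 20.5, 100.75, 120.0, 0.5)]
        write_boxes(boxes, tmp_path / "a.txt", w, h)
        (back,) = read_boxes(tmp_path / "a.txt", w, h)
        for attr in ("x_min", "y_min", "x_max", "y_max"):
            assert abs(getattr(back, attr) - getattr(boxes[0], attr)) <= 0.5

    def test_malformed_line_rejected(self, tmp_path):
        (tmp_path / "b.txt").write_text("0 0.5 0.5\n")
        with pytest.raises(ValueError):
            read_boxes(tmp_path / "b.txt", 100, 100)

    def test_out_of_range_value_rejected(self, tmp_path):
        (tmp_path / "b.txt").write_text("0 1.5 0.5 0.2 0.2\n")
        with pytest.raises(ValueError):
            read_boxes(tmp_path / "b.txt", 100, 100)


def _nms_reference(boxes, thr):
    """Exhaustive greedy reference: explicit list removal, no shortcuts."""
    remaining = list(boxes)
    kept = []
    while remaining:
        best = max(remaining, key=lambda b: b.confidence)
        # stable tie-break: earliest in the original list
        ties = [b for b in remaining if b.confidence == best.confidence]
        best = min(ties, key=lambda b: boxes.index(b))
        kept.append(best)
        remaining = [b for b in remaining if b is not best and box_iou(best, b) <= thr]
    return kept


class TestNms:
    def test_single_box_unchanged(self):
        b = Box(0, 0, 10, 10, 0.7)
        assert nms([b], 0.5) == [b]

    def test_exact_duplicate_suppressed(self):
        hi = Box(0, 0, 10, 10, 0.9)
        lo = Box(0, 0, 10, 10, 0.8)
        assert nms([hi, lo], 0.5) == [hi]

    def test_matches_exhaustive_reference(self, rng):
        boxes = []
        for _ in range(50):
            x0, y0 = rng.uniform(0, 80), rng.uniform(0, 80)
            boxes.append(Box(x0, y0, x0 + rng.uniform(5, 30), y0 + rng.uniform(5, 30),
                             float(rng.uniform(0, 1))))
        for thr in (0.1, 0.3, 0.5, 0.9):
            assert nms(boxes, thr) == _nms_reference(boxes, thr)

    def test_survivors_have_bounded_pairwise_iou(self, rng):
        boxes = []
        for _ in range(40):
            x0, y0 = rng.uniform(0, 50), rng.uniform(0, 50)
            boxes.append(Box(x0, y0, x0 + rng.uniform(5, 25), y0 + rng.uniform(5, 25),
                             float(rng.uniform(0, 1))))
        kept = nms(boxes, 0.4)
        assert all(b in boxes for b in kept)
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                assert box_iou(a, b) <= 0.4


class TestBoxBasics:
    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            Box(5, 5, 5, 10)

    def test_boxes_mask_covers_rounded_extent(self):
        mask = boxes_mask([Box(1.2, 2.0, 3.8, 4.0)], 10, 10)
        assert mask[2:4, 1:4].all()
        assert mask.sum() == 2 * 3

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(1, 50), st.integers(1, 50))
    def test_iou_self_is_one(self, x, y, w, h):
        b = Box(x, y, x + w, y + h)
        assert box_iou(b, b) == pytest.approx(1.0)
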