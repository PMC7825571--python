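"""Segmentation stage: background subtraction, Otsu, morphology, blobs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mothtrap.segmentation import (
    Detection,
    SegmentationConfig,
    binarize_otsu,
    extract_detections,
    foreground,
    morph_clean,
    motion_gate,
    segment_frame,
)


def _disk(shape, center, radius):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius ** 2


def otsu_oracle(gray):
    """Exhaustive threshold sweep maximizing between-class variance (8-bit)."""
    values = np.asarray(gray).ravel()
    best_t, best_var = None, -1.0
    for t in np.unique(values)[:-1]:
        lo, hi = values[values <= t], values[values > t]
        w0, w1 = lo.size / values.size, hi.size / values.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


class TestMotionGate:
    def test_identical_frames_do_not_trigger(self):
        frame = np.full((100, 100), 200, dtype=np.uint8)
        assert motion_gate(frame, frame, threshold=1500) is False

    @pytest.mark.parametrize("threshold,expected", [(1500, True), (2500, False)])
    def test_planted_patch_counted_exactly(self, threshold, expected):
        # 50x50 fully-changed patch = 2500 changed pixels; trigger is strict >
        prev = np.full((200, 200), 230, dtype=np.uint8)
        curr = prev.copy()
        curr[10:60, 10:60] = 40
        assert motion_gate(curr, prev, threshold=threshold) is expected

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            motion_gate(np.zeros((10, 10)), np.zeros((10, 12)), 0)


class TestForeground:
    def test_identical_image_gives_zero(self):
        img = np.random.default_rng(0).integers(0, 255, (40, 40, 3), dtype=np.uint8)
        assert np.all(foreground(img, img) == 0)

    def test_support_is_the_planted_disk(self):
        background = np.full((80, 80, 3), 255, dtype=np.uint8)
        image = background.copy()
        mask = _disk((80, 80), (40, 40), 15)
        image[mask] = 0
        fg = foreground(image, background)
        assert np.all(fg[mask] > 0)
        assert np.all(fg[~mask] == 0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 255, (30, 30, 3), dtype=np.uint8)
        b = rng.integers(0, 255, (30, 30, 3), dtype=np.uint8)
        assert np.array_equal(foreground(a, b), foreground(b, a))


class TestOtsu:
    def test_bimodal_raster_splits_exactly(self):
        rng = np.random.default_rng(2)
        gray = np.where(rng.random((60, 60)) < 0.9, 10, 200).astype(np.uint8)
        out = binarize_otsu(gray)
        assert np.array_equal(out, gray == 200)

    def test_constant_raster_is_all_background(self):
        assert not binarize_otsu(np.zeros((10, 10))).any()
        assert not binarize_otsu(np.full((10, 10), 77)).any()

    def test_inverted_contrast_gives_complement(self):
        rng = np.random.default_rng(3)
        gray = np.where(rng.random((60, 60)) < 0.8, 20, 220).astype(np.uint8)
        out = binarize_otsu(gray)
        out_inv = binarize_otsu(255 - gray)
        assert np.array_equal(out, ~out_inv)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_threshold_matches_sweep_oracle(self, seed):
        """Otsu equals the exhaustive between-class-variance sweep."""
        rng = np.random.default_rng(seed)
        n_modes = rng.integers(2, 4)
        parts = [rng.normal(rng.uniform(0, 255), rng.uniform(2, 30), 400)
                 for _ in range(n_modes)]
        gray = np.clip(np.concatenate(parts), 0, 255).astype(np.uint8).reshape(-1, 40)
        if np.ptp(gray) == 0:
            return
        t = otsu_oracle(gray)
        assert np.array_equal(binarize_otsu(gray), gray > t)


class TestMorphClean:
    def test_isolated_pixel_removed_by_opening(self):
        binary = np.zeros((30, 30), dtype=bool)
        binary[15, 15] = True
        cfg = SegmentationConfig(open_kernel=3, close_kernel=0)
        assert not morph_clean(binary, cfg).any()

    def test_opening_equals_erosion_then_dilation(self):
        from scipy import ndimage
        disk = _disk((120, 120), (60, 60), 50)
        cfg = SegmentationConfig(open_kernel=3, close_kernel=0)
        se = np.ones((3, 3), dtype=bool)
        expected = ndimage.binary_dilation(ndimage.binary_erosion(disk, se), se)
        assert np.array_equal(morph_clean(disk, cfg), expected)

    def test_closing_fills_small_hole(self):
        disk = _disk((60, 60), (30, 30), 20)
        disk[30, 30] = False
        cfg = SegmentationConfig(open_kernel=0, close_kernel=3)
        assert morph_clean(disk, cfg)[30, 30]


class TestExtractDetections:
    def test_empty_raster_gives_no_detections(self):
        assert extract_detections(np.zeros((50, 50), dtype=bool)) == []

    def test_three_planted_disks_found_with_known_boxes(self):
        binary = np.zeros((400, 400), dtype=bool)
        centers = [(80, 80), (200, 300), (320, 120)]
        for cx, cy in centers:
            binary |= _disk(binary.shape, (cx, cy), 40)
        cfg = SegmentationConfig(min_blob_area=100)
        dets = extract_detections(binary, frame_index=3, config=cfg)
        assert len(dets) == 3
        assert all(d.frame_index == 3 for d in dets)
        # ordered by (y_min, x_min); bbox of a radius-40 disk is 81 px wide
        for det, (cx, cy) in zip(dets, [(80, 80), (320, 120), (200, 300)]):
            x, y, w, h = det.bbox
            assert (x, y, w, h) == (cx - 40, cy - 40, 81, 81)
            assert det.centroid == (x + w / 2, y + h / 2)

    def test_overlapping_disks_merge_into_one_detection(self):
        # known failure mode: individuals too close together become one blob
        binary = _disk((200, 200), (90, 100), 40) | _disk((200, 200), (130, 100), 40)
        dets = extract_detections(binary, config=SegmentationConfig(min_blob_area=100))
        assert len(dets) == 1

    def test_min_area_filter_excludes_small_blobs(self):
        binary = _disk((200, 200), (50, 50), 40) | _disk((200, 200), (150, 150), 5)
        cfg = SegmentationConfig(min_blob_area=1000)
        assert len(extract_detections(binary, config=cfg)) == 1


class TestSegmentFrame:
    def test_frame_equal_to_background_gives_nothing(self):
        bg = np.full((100, 100, 3), 235, dtype=np.uint8)
        assert segment_frame(bg, bg) == []

    def test_recovers_planted_insect_count(self, small_scene):
        frames, background, truth = small_scene
        cfg = SegmentationConfig()
        for i, frame in enumerate(frames[:4]):
            dets = segment_frame(frame, background, cfg, frame_index=i)
            expected = (truth.frame_index == i).sum()
            assert len(dets) == expected

    def test_detections_lie_inside_frame_with_central_centroids(self, small_scene):
        frames, background, _ = small_scene
        h, w = frames[0].shape[:2]
        for det in segment_frame(frames[0], background):
            x, y, bw, bh = det.bbox
            assert 0 <= x and x + bw <= w and 0 <= y and y + bh <= h
            assert det.centroid == (x + bw / 2, y + bh / 2)

    def test_deterministic(self, small_scene):
        frames, background, _ = small_scene
        a = segment_frame(frames[1], background)
        b = segment_frame(frames[1], background)
        assert a == b


class TestDetectionInvariants:
    def test_degenerate_bbox_rejected(self):
        with pytest.raises(ValueError):
            Detection(0, (5, 5, 0, 10), (5, 10), 10)

    def test_centroid_outside_bbox_rejected(self):
        with pytest.raises(ValueError):
            Detection(0, (5, 5, 10, 10), (50, 50), 10)
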