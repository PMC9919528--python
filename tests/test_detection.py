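"""Detector stages against brute-force pixel oracles, plus the full pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import ndimage

import swarmsense as ss
from swarmsense.detection import DetectorConfig, denoise

frames_8bit = hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 255))


class TestFrameDifference:
    def test_identical_frames_zero_mask(self):
        f = np.full((6, 6), 77, dtype=np.uint8)
        assert not ss.frame_difference(f, f, 25).any()

    def test_threshold_boundary_single_pixel(self):
        a = np.zeros((5, 5), dtype=np.uint8)
        b = a.copy()
        b[2, 3] = 26  # Th + 1: strictly greater fires
        mask = ss.frame_difference(a, b, 25)
        assert mask.sum() == 1 and mask[2, 3]
        b[2, 3] = 25  # exactly Th: does not fire
        assert not ss.frame_difference(a, b, 25).any()

    def test_moved_block_matches_pixel_loop(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        a[2:5, 1:4] = 200
        b = np.zeros((8, 8), dtype=np.uint8)
        b[2:5, 3:6] = 200
        mask = ss.frame_difference(a, b, 25)
        expected = np.zeros((8, 8), dtype=bool)
        for y in range(8):  # independent per-pixel oracle
            for x in range(8):
                expected[y, x] = abs(int(a[y, x]) - int(b[y, x])) > 25
        np.testing.assert_array_equal(mask, expected)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=frames_8bit, b=frames_8bit)
    def test_symmetric_in_arguments(self, a, b):
        np.testing.assert_array_equal(
            ss.frame_difference(a, b, 25), ss.frame_difference(b, a, 25)
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ss.frame_difference(np.zeros((4, 4)), np.zeros((5, 5)), 25)


class TestBackgroundModel:
    def test_degenerate_rates(self, rng):
        bg = rng.integers(0, 255, (6, 6)).astype(float)
        frame = rng.integers(0, 255, (6, 6)).astype(np.uint8)
        np.testing.assert_allclose(ss.update_background(bg, frame, 1.0), frame)
        np.testing.assert_allclose(ss.update_background(bg, frame, 0.0), bg)

    def test_geometric_decay_to_constant_stream(self):
        bg = np.full((4, 4), 200.0)
        frame = np.full((4, 4), 40, dtype=np.uint8)
        for k in range(1, 12):
            bg = ss.update_background(bg, frame, 0.5)
            expected = 0.5**k * 160.0
            assert abs(np.abs(bg - 40.0).max() - expected) < 1e-9

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError, match="alpha"):
            ss.update_background(np.zeros((2, 2)), np.zeros((2, 2)), 1.5)

    def test_moving_average_mask_brute_force(self, rng):
        frame = rng.integers(0, 255, (16, 16)).astype(np.uint8)
        bg = rng.uniform(0, 255, (16, 16))
        mask = ss.moving_average_mask(frame, bg, 25)
        expected = np.abs(frame.astype(float) - bg) > 25
        np.testing.assert_array_equal(mask, expected)


class TestFuseMasks:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(a=hnp.arrays(bool, (8, 8)), b=hnp.arrays(bool, (8, 8)))
    def test_commutative_and_subset_of_inputs(self, a, b):
        fused = ss.fuse_masks(a, b)
        np.testing.assert_array_equal(fused, ss.fuse_masks(b, a))
        assert not np.any(fused & ~a)
        assert not np.any(fused & ~b)

    def test_annihilator_and_identity(self, rng):
        m = rng.random((6, 6)) > 0.5
        assert not ss.fuse_masks(m, np.zeros((6, 6), bool)).any()
        np.testing.assert_array_equal(ss.fuse_masks(m, np.ones((6, 6), bool)), m)


def _oracle_erode(mask: np.ndarray, k: int) -> np.ndarray:
    """Independent erosion: a pixel survives iff its full kxk neighbourhood
    (anchored like scipy's origin) is set."""
    h, w = mask.shape
    pad = np.zeros((h + k - 1, w + k - 1), dtype=bool)
    lo = (k - 1) // 2
    pad[lo : lo + h, lo : lo + w] = mask
    out = np.ones_like(mask)
    for dy in range(k):
        for dx in range(k):
            out &= pad[dy : dy + h, dx : dx + w]
    return out


def _oracle_dilate(mask: np.ndarray, k: int) -> np.ndarray:
    h, w = mask.shape
    pad = np.zeros((h + k - 1, w + k - 1), dtype=bool)
    lo = (k - 1) // 2
    pad[lo : lo + h, lo : lo + w] = mask
    out = np.zeros_like(mask)
    for dy in range(k):
        for dx in range(k):
            out |= pad[k - 1 - dy : k - 1 - dy + h, k - 1 - dx : k - 1 - dx + w]
    return out


class TestDenoise:
    def test_empty_mask_stays_empty(self):
        assert not denoise(np.zeros((20, 20), bool)).any()

    def test_unit_opening_is_identity(self, rng):
        mask = rng.random((15, 15)) > 0.5
        opened = ndimage.binary_opening(mask, structure=np.ones((1, 1), bool))
        np.testing.assert_array_equal(opened, mask)

    def test_square_survives_speckle_dies(self, rng):
        square = np.zeros((64, 64), dtype=bool)
        square[10:30, 10:30] = True  # 20x20 solid block
        mask = square.copy()
        placed = 0
        while placed < 30:  # isolated single-pixel speckles away from the block
            y, x = rng.integers(0, 64, size=2)
            if (8 <= y <= 32 and 8 <= x <= 32) or mask[
                max(y - 1, 0) : y + 2, max(x - 1, 0) : x + 2
            ].any():
                continue
            mask[y, x] = True
            placed += 1
        out = denoise(mask)
        _, n = ndimage.label(out, structure=np.ones((3, 3)))
        assert n == 1
        # survivor = the block eroded twice by 3x3 (independent oracle);
        # speckles cannot survive two erosions
        expected = _oracle_erode(_oracle_erode(square, 3), 3)
        np.testing.assert_array_equal(out, expected)

    def test_erosion_stage_matches_oracle(self, rng):
        mask = rng.random((40, 40)) > 0.6
        eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
        np.testing.assert_array_equal(eroded, _oracle_erode(mask, 3))
        dilated = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
        np.testing.assert_array_equal(dilated, _oracle_dilate(mask, 3))

    def test_erosion_anti_extensive_vs_first_two_stages(self, clean_scene):
        _, frames, _ = clean_scene
        cfg = DetectorConfig()
        bs = ss.frame_difference(frames.frames[5], frames.frames[4], cfg.th)
        ma = ss.moving_average_mask(frames.frames[5], frames.frames[0].astype(float), cfg.th)
        fused = ss.fuse_masks(bs, ma)
        stage2 = fused
        for _ in range(cfg.close1_iters):
            stage2 = ndimage.binary_closing(stage2, structure=np.ones(cfg.close_kernel, bool))
        for _ in range(cfg.open_iters):
            stage2 = ndimage.binary_opening(stage2, structure=np.ones(cfg.open_kernel, bool))
        assert denoise(fused, cfg).sum() <= stage2.sum()


class TestExtractCentroids:
    def test_empty_mask(self):
        assert ss.extract_centroids(np.zeros((10, 10), bool)) == []

    def test_square_centroid(self):
        mask = np.zeros((50, 50), dtype=bool)
        mask[20:30, 20:30] = True  # top-left corner (20, 20)
        (det,) = ss.extract_centroids(mask)
        assert det.x == pytest.approx(24.5)
        assert det.y == pytest.approx(24.5)
        assert det.area == 100

    def test_min_area_filters_and_centroid_matches_pixel_mean(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[5:8, 5:8] = True  # area 9 -> filtered
        mask[20:25, 18:23] = True  # area 25 -> kept
        dets = ss.extract_centroids(mask, min_blob_area=10)
        assert len(dets) == 1
        ys, xs = np.nonzero(np.pad(np.ones((5, 5), bool), ((20, 15), (18, 17))))
        assert dets[0].x == pytest.approx(xs.mean())
        assert dets[0].y == pytest.approx(ys.mean())


class TestDetectSequence:
    def test_static_scene_no_detections(self):
        frame = np.full((60, 80), 90, dtype=np.uint8)
        seq = ss.FrameSequence(frames=np.stack([frame] * 6), timestamps=np.arange(6.0))
        dets = ss.detect_sequence(seq)
        assert all(len(d) == 0 for d in dets)

    def test_too_few_frames_rejected(self):
        seq = ss.FrameSequence(frames=np.zeros((1, 10, 10), np.uint8), timestamps=[0.0])
        with pytest.raises(ValueError, match="2 frames"):
            ss.detect_sequence(seq)

    def test_deterministic(self, clean_scene, clean_detections):
        _, frames, _ = clean_scene
        again = ss.detect_sequence(frames)
        assert len(again) == len(clean_detections)
        for a, b in zip(again, clean_detections):
            np.testing.assert_array_equal(a.centroids(), b.centroids())

    def test_single_fish_centroid_error(self):
        cfg = ss.SwarmSimConfig(n_fish=1, steps=30, seed=3, base_heading=0.5)
        traj = ss.simulate_swarm(ss.SwarmPattern.PARALLEL, cfg)
        frames, truth = ss.render_frames(traj, ss.NoiseConfig.none(), fish_radius=5)
        score = ss.score_detections(truth[1:], ss.detect_sequence(frames))
        assert score.recall >= 0.9
        assert score.mean_centroid_error <= 3.0

    def test_five_fish_counted(self, clean_scene, clean_detections):
        counts = [len(d) for d in clean_detections]
        assert np.mean([c == 5 for c in counts]) >= 0.9

    def test_headings_follow_motion(self, clean_scene, clean_detections):
        traj, _, _ = clean_scene
        headings = [
            d.heading
            for ds in clean_detections[5:]
            for d in ds.detections
            if d.heading is not None
        ]
        assert len(headings) > 100
        # school travels along base_heading=0.3; detected headings agree
        err = np.abs(np.angle(np.exp(1j * (np.array(headings) - 0.3))))
        assert np.median(err) < 0.3
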