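"""Binarization/postprocessing contracts, classical baselines, and the trainer."""

import numpy as np
import pytest

from spintrack.metrics import iou
from spintrack.segmentation import (
    TrainConfig,
    TrainedSegmenter,
    binarize,
    build_segmenter,
    kmeans_segment,
    levelset_segment,
    postprocess_mask,
    predict_mask,
    threshold_segment,
    train_segmenter,
)
from spintrack.synthcell import NoiseModel, SynthParams, generate_training_set, render_frame

COARSE = SynthParams(pixel_size_um=0.25)  # 4-5 um head fits a 32 px crop


class TestBinarize:
    def test_threshold_is_inclusive(self):
        p = np.full((2, 4, 4), 0.5)
        assert binarize(p, 0.5).all()

    def test_exact_probabilities_reproduce_truth(self, rng):
        truth = rng.random((6, 6)) > 0.5
        p = np.stack([~truth, truth]).astype(float)
        np.testing.assert_array_equal(binarize(p), truth)

    def test_unreachable_threshold_gives_empty_mask(self):
        p = np.stack([np.full((4, 4), 0.2), np.full((4, 4), 0.8)])
        assert not binarize(p, 0.9).any()

    def test_idempotent(self, rng):
        p = rng.random((2, 5, 5))
        once = binarize(p)
        np.testing.assert_array_equal(binarize(once.astype(float)), once)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 3, 3)), 1.0)


class TestPostprocess:
    def test_keeps_largest_component_only(self):
        m = np.zeros((30, 30), bool)
        m[2:12, 2:12] = True   # 100 px
        m[20:26, 20:25] = True  # 30 px
        out, ok = postprocess_mask(m, 10)
        assert ok
        assert out[2:12, 2:12].all() and not out[20:26, 20:25].any()

    def test_small_blob_flagged_invalid(self):
        m = np.zeros((20, 20), bool)
        m[3, 3:8] = True  # 5 px
        out, ok = postprocess_mask(m, 20)
        assert not ok and not out.any()

    def test_matches_flood_fill_oracle(self, rng):
        def flood_fill_largest(mask):
            seen = np.zeros_like(mask, bool)
            best = 0
            for r0, c0 in np.argwhere(mask):
                if seen[r0, c0]:
                    continue
                stack, size = [(r0, c0)], 0
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                    and mask[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack.append((rr, cc))
                best = max(best, size)
            return best

        for _ in range(10):
            m = rng.random((25, 25)) > 0.7
            out, ok = postprocess_mask(m, 1)
            assert out.sum() == flood_fill_largest(m)

    def test_idempotent(self, rng):
        m = rng.random((25, 25)) > 0.6
        once, ok1 = postprocess_mask(m, 5)
        twice, ok2 = postprocess_mask(once, 5)
        np.testing.assert_array_equal(once, twice)
        assert ok1 == ok2


class TestClassicalBaselines:
    def _two_valued(self):
        frame = np.full((60, 60), 0.2)
        truth = np.zeros((60, 60), bool)
        truth[20:40, 15:45] = True
        frame[truth] = 0.9
        return frame, truth

    def test_kmeans_separable_case_exact(self):
        frame, truth = self._two_valued()
        np.testing.assert_array_equal(kmeans_segment(frame), truth)

    def test_kmeans_constant_frame_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            kmeans_segment(np.full((10, 10), 0.5))

    def test_levelset_separable_case(self):
        frame, truth = self._two_valued()
        assert iou(levelset_segment(frame, iterations=80), truth) >= 0.95

    def test_levelset_single_iteration_returns_mask(self):
        frame, _ = self._two_valued()
        out = levelset_segment(frame, iterations=1)
        assert out.dtype == bool and out.shape == frame.shape

    def test_otsu_threshold_separable_case(self):
        frame, truth = self._two_valued()
        np.testing.assert_array_equal(threshold_segment(frame), truth)

    def test_noise_degrades_kmeans_more_than_clean(self):
        clean = SynthParams(seed=8, background_noise=NoiseModel(0.0, 0, 0.0))
        noisy = SynthParams(seed=8, background_noise=NoiseModel(0.08, 10, 0.6))
        fc, mc, _ = render_frame(clean, 0)
        fn, mn, _ = render_frame(noisy, 0)
        iou_clean = iou(postprocess_mask(kmeans_segment(fc), 20)[0], mc)
        iou_noisy = iou(postprocess_mask(kmeans_segment(fn), 20)[0], mn)
        assert iou_clean >= 0.8
        assert iou_noisy < iou_clean


@pytest.fixture(scope="module")
def small_trained():
    """A small trained model shared by the trainer tests (64x64, depth 3)."""
    pairs = generate_training_set(n_images=24, seed=3, image_size=64)
    cfg = TrainConfig(depth=3, base_channels=4, epochs=14, seed=0)
    model, report = train_segmenter(pairs, cfg)
    return pairs, cfg, model, report


class TestTrainer:
    def test_training_improves_on_untrained(self, small_trained):
        pairs, cfg, model, report = small_trained
        untrained = build_segmenter(cfg)
        frame, truth = pairs[0]
        trained_iou = iou(binarize(predict_mask(model, frame)), truth)
        untrained_iou = iou(binarize(predict_mask(untrained, frame)), truth)
        assert trained_iou > untrained_iou
        assert report.mean_iou > 0.8

    def test_heldout_iou_reported(self, small_trained):
        _, _, _, report = small_trained
        assert len(report.fold_ious) == 1
        assert 0.0 <= report.mean_iou <= 1.0

    def test_predict_shape_and_normalization(self, small_trained):
        _, _, model, _ = small_trained
        p = predict_mask(model, np.random.default_rng(0).random((150, 150)))
        assert p.shape == (2, 150, 150)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-5)

    def test_predict_pads_odd_sizes(self, small_trained):
        _, _, model, _ = small_trained
        p = predict_mask(model, np.random.default_rng(0).random((37, 41)))
        assert p.shape == (2, 37, 41)

    def test_constant_frame_yields_near_uniform_map(self, small_trained):
        _, _, model, _ = small_trained
        p = predict_mask(model, np.full((64, 64), 0.5))
        # spatially near-uniform: interior probability variation is tiny
        interior = p[1, 8:-8, 8:-8]
        assert interior.std() < 0.2

    def test_non_2d_input_rejected(self, small_trained):
        _, _, model, _ = small_trained
        with pytest.raises(ValueError, match="2-D"):
            predict_mask(model, np.zeros((3, 64, 64)))

    def test_checkpoint_roundtrip(self, small_trained, tmp_path):
        pairs, _, model, _ = small_trained
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedSegmenter.load(path)
        frame = pairs[0][0]
        np.testing.assert_array_equal(
            predict_mask(loaded, frame), predict_mask(model, frame)
        )
        assert loaded.config == model.config

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_segmenter([], TrainConfig())

    def test_size_mismatch_rejected(self):
        bad = [(np.zeros((32, 32)), np.zeros((16, 16), bool))]
        with pytest.raises(ValueError, match="mismatch"):
            train_segmenter(bad, TrainConfig())

    def test_too_few_samples_for_cv_rejected(self):
        pairs = generate_training_set(n_images=3, seed=0, image_size=32, template=COARSE)
        with pytest.raises(ValueError, match="fold"):
            train_segmenter(pairs, TrainConfig(cv_folds=5))

    def test_identical_seeds_reproduce_training(self):
        pairs = generate_training_set(n_images=6, seed=1, image_size=32, template=COARSE)
        cfg = TrainConfig(depth=2, base_channels=2, epochs=2, seed=5)
        m1, r1 = train_segmenter(pairs, cfg)
        m2, r2 = train_segmenter(pairs, cfg)
        assert r1.fold_ious == r2.fold_ious
        for k, v in m1.net.state_arrays().items():
            np.testing.assert_array_equal(v, m2.net.state_arrays()[k])

    def test_cross_validation_reports_per_fold(self):
        pairs = generate_training_set(n_images=8, seed=2, image_size=32, template=COARSE)
        cfg = TrainConfig(depth=2, base_channels=2, epochs=2, cv_folds=2, seed=0)
        model, report = train_segmenter(pairs, cfg)
        assert len(report.fold_ious) == 2
        assert report.epochs_used >= 1
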