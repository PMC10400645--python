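"""ROI geometry, ellipse-fit recovery against the rasterization oracle, and
phase unwrapping across the 0/180 axis ambiguity."""

import numpy as np
import pytest

from spintrack.orientation import (
    EllipsePose,
    RoiSpec,
    extract_roi,
    fit_ellipse,
    phase_signal,
    track_roi,
    unwrap_phase,
    wrap_increment,
)
from spintrack.synthcell import SynthParams, generate_sequence, rasterize_ellipse


class TestExtractRoi:
    def test_half_open_crop_arithmetic(self):
        frame = np.arange(300 * 300, dtype=float).reshape(300, 300)
        win = extract_roi(frame, RoiSpec(center=(150, 150), size=150))
        assert win.origin == (75, 75)
        np.testing.assert_array_equal(win.image, frame[75:225, 75:225])
        assert not win.padded

    def test_edge_crop_is_padded_and_flagged(self):
        frame = np.ones((300, 300))
        win = extract_roi(frame, RoiSpec(center=(10, 10), size=150))
        assert win.padded
        assert win.image.shape == (150, 150)
        assert win.image[0, 0] == 0.0  # zero padding top-left

    def test_reembedding_reproduces_pixels(self):
        rng = np.random.default_rng(0)
        frame = rng.random((200, 200))
        win = extract_roi(frame, RoiSpec(center=(100, 100), size=64))
        r0, c0 = win.origin
        np.testing.assert_array_equal(frame[r0 : r0 + 64, c0 : c0 + 64], win.image)

    def test_center_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_roi(np.ones((50, 50)), RoiSpec(center=(100, 10), size=32))

    def test_too_small_roi_rejected(self):
        with pytest.raises(ValueError, match="size"):
            RoiSpec(center=(10, 10), size=16)


class TestFitEllipse:
    @pytest.mark.parametrize("alpha", [0.0, 10.0, 40.0, 89.5, 90.5, 139.0, 179.0])
    def test_recovers_rasterized_orientation_and_axes(self, ellipse_mask, alpha):
        pose = fit_ellipse(ellipse_mask(alpha))
        assert pose.valid and pose.eccentricity_ok
        diff = abs(wrap_increment(pose.alpha - alpha))
        assert diff <= 1.0
        assert pose.a == pytest.approx(25.0, rel=0.05)
        assert pose.b == pytest.approx(12.0, rel=0.05)

    def test_circle_has_untrusted_orientation(self, ellipse_mask):
        pose = fit_ellipse(ellipse_mask(0.0, a=15.0, b=15.0))
        assert pose.valid
        assert not pose.eccentricity_ok

    def test_tiny_mask_is_invalid_not_an_exception(self):
        m = np.zeros((20, 20), bool)
        m[5, 5:8] = True
        pose = fit_ellipse(m)
        assert not pose.valid

    def test_empty_mask_is_invalid(self):
        assert not fit_ellipse(np.zeros((20, 20), bool)).valid

    @pytest.mark.parametrize("theta", [10.0, 45.0, 90.0])
    def test_rotation_equivariance(self, ellipse_mask, theta):
        base = fit_ellipse(ellipse_mask(20.0)).alpha
        rotated = fit_ellipse(ellipse_mask(20.0 + theta)).alpha
        assert abs(wrap_increment(rotated - base - theta)) <= 1.0

    def test_translation_moves_center_not_angle(self, ellipse_mask):
        p0 = fit_ellipse(ellipse_mask(40.0, center=(60.0, 60.0)))
        p1 = fit_ellipse(ellipse_mask(40.0, center=(80.0, 65.0)))
        assert p1.cx - p0.cx == pytest.approx(20.0, abs=0.2)
        assert p1.cy - p0.cy == pytest.approx(5.0, abs=0.2)
        assert abs(wrap_increment(p1.alpha - p0.alpha)) < 0.1

    def test_center_recovery(self, ellipse_mask):
        pose = fit_ellipse(ellipse_mask(70.0, center=(64.0, 90.0)))
        assert pose.cx == pytest.approx(64.0, abs=0.5)
        assert pose.cy == pytest.approx(90.0, abs=0.5)


class TestPhaseSignal:
    def _poses(self, alphas, circular_at=()):
        poses = []
        for k, a in enumerate(alphas):
            p = EllipsePose(cx=0, cy=0, a=25, b=12, alpha=a, valid=True, eccentricity_ok=True)
            if k in circular_at:
                p.eccentricity_ok = False
            poses.append(p)
        return poses

    def test_all_valid_has_no_missing(self):
        track = phase_signal(self._poses([10, 20, 30]), fps=163.0)
        assert not np.isnan(track.alpha_raw).any()

    def test_circular_frame_marked_missing(self):
        track = phase_signal(self._poses([10, 20, 30], circular_at={1}), fps=163.0)
        assert np.isnan(track.alpha_raw[1])
        assert not np.isnan(track.alpha_raw[[0, 2]]).any()

    def test_fewer_than_two_valid_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            phase_signal(self._poses([10, 20], circular_at={0}), fps=163.0)

    def test_fewer_than_two_poses_rejected(self):
        with pytest.raises(ValueError):
            phase_signal(self._poses([10]), fps=163.0)


class TestUnwrap:
    def _track(self, alphas):
        poses = [
            EllipsePose(cx=0, cy=0, a=2, b=1, alpha=a, valid=True, eccentricity_ok=True)
            if a is not None
            else EllipsePose()
            for a in alphas
        ]
        return phase_signal(poses, fps=163.0)

    def test_forward_boundary_crossing(self):
        # 178 -> 2 is a +4 degree step, not -176
        track = unwrap_phase(self._track([178.0, 2.0]))
        assert track.alpha_unwrapped[1] - track.alpha_unwrapped[0] == pytest.approx(4.0)

    def test_backward_boundary_crossing(self):
        track = unwrap_phase(self._track([2.0, 178.0]))
        assert track.alpha_unwrapped[1] - track.alpha_unwrapped[0] == pytest.approx(-4.0)

    def test_no_wrap_simple_step(self):
        track = unwrap_phase(self._track([10.0, 20.0]))
        assert track.alpha_unwrapped[1] - track.alpha_unwrapped[0] == pytest.approx(10.0)

    def test_constant_alpha_stays_constant(self):
        track = unwrap_phase(self._track([77.0] * 5))
        np.testing.assert_allclose(np.diff(track.alpha_unwrapped), 0.0, atol=1e-12)

    def test_exact_90_tie_breaks_positive(self):
        track = unwrap_phase(self._track([0.0, 90.0]))
        assert track.alpha_unwrapped[1] - track.alpha_unwrapped[0] == pytest.approx(90.0)

    def test_increments_bounded_and_mod_invariant(self):
        rng = np.random.default_rng(3)
        alphas = rng.uniform(0, 180, 50).tolist()
        track = unwrap_phase(self._track(alphas))
        d = np.diff(track.alpha_unwrapped)
        assert ((d > -90) & (d <= 90)).all()
        np.testing.assert_allclose(
            track.alpha_unwrapped % 180.0, track.alpha_raw, atol=1e-9
        )

    def test_gap_is_recorded_and_spans_no_pair(self):
        track = unwrap_phase(self._track([10.0, None, 30.0]))
        assert track.gap_pairs == [(0, 2)]
        assert np.isnan(track.alpha_unwrapped[1])

    def test_cumulative_phase_matches_constant_rotation(self):
        # both rotation senses, crossing the 0/180 boundary many times
        for omega in (2.0, -2.0):
            step = omega * 360.0 / 163.0
            truth = 170.0 + step * np.arange(120)
            track = unwrap_phase(self._track(list(truth % 180.0)))
            recovered = track.alpha_unwrapped - track.alpha_unwrapped[0]
            np.testing.assert_allclose(recovered, truth - truth[0], atol=1e-6)


class TestTrackRoi:
    def test_static_cell_tracked_within_one_pixel(self):
        from spintrack.synthcell import NoiseModel

        p = SynthParams(
            omega_true=1.0, seed=4, frame_size=(150, 150),
            background_noise=NoiseModel(0.02, 0, 0.0),
        )
        frames, gt = generate_sequence(p, 8)
        specs = track_roi(frames, tuple(gt.center_true[0]), lambda roi: roi > 0.5, size=64)
        for spec, c in zip(specs, gt.center_true):
            assert abs(spec.center[0] - c[0]) <= 1.0
            assert abs(spec.center[1] - c[1]) <= 1.0

    def test_translating_cell_lags_at_most_one_step(self):
        # object moving 2 px/frame along +col; provider segments by threshold
        n, h, w = 10, 100, 100
        frames = np.zeros((n, h, w))
        centers = []
        for k in range(n):
            c = (30.0 + 2.0 * k, 50.0)
            centers.append(c)
            frames[k] = rasterize_ellipse((h, w), np.array(c), 10, 5, 0.0).astype(float)
        specs = track_roi(frames, centers[0], lambda roi: roi > 0.5, size=64)
        for k in range(1, n):
            lag = abs(specs[k].center[0] - centers[k][0])
            assert lag <= 2.0 + 1e-9

    def test_fixed_mode_keeps_center(self):
        frames = np.zeros((5, 64, 64))
        specs = track_roi(frames, (32, 32), lambda roi: roi > 0.5, size=32, mode="fixed")
        assert all(s.center == (32.0, 32.0) for s in specs)

    def test_all_invalid_rejected(self):
        frames = np.zeros((4, 64, 64))
        with pytest.raises(ValueError, match="tracking failed"):
            track_roi(frames, (32, 32), lambda roi: roi > 0.5, size=32, mode="tracking")


class TestRoundTrip:
    def test_synthetic_phase_recovery_within_tolerance(self):
        # clean sequence, |omega| < fps/4: unwrapped phase matches k*omega*360/fps
        from spintrack.synthcell import NoiseModel

        p = SynthParams(
            omega_true=3.0, alpha0_deg=15.0, seed=6,
            background_noise=NoiseModel(0.0, 0, 0.0), psf_sigma_px=0.5,
        )
        frames, gt = generate_sequence(p, 100)
        poses = [fit_ellipse(m) for m in gt.masks]
        track = unwrap_phase(phase_signal(poses, fps=p.fps))
        expected = np.arange(100) * 3.0 * 360.0 / 163.0
        recovered = track.alpha_unwrapped - track.alpha_unwrapped[0]
        assert np.abs(recovered - expected).max() <= 2.0
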