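"""End-to-end rotation analysis: ROI -> segmentation -> ellipse fit -> speed.

A fully-defaulted :class:`PipelineConfig` reproduces the trapped-cell study
conditions: 163 fps recording, a fixed 150 x 150 px ROI at the trap center,
probability threshold 0.5, and the eccentricity gate a/b >= 1.1 on fitted
poses.  Swap ``roi_mode`` to "tracking" for free-swimming cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import kinematics, orientation, segmentation
from .io import FrameStack

log = logging.getLogger("spintrack")


@dataclass
class PipelineConfig:
    fps: float = 163.0
    roi_size: int = 150
    roi_mode: str = "fixed"            # "fixed" | "tracking"
    roi_center: tuple[float, float] | None = None  # None: frame center
    method: str = "learned"            # "learned" | "kmeans" | "levelset" | "threshold"
    model: segmentation.TrainedSegmenter | None = None
    binarize_threshold: float = 0.5
    min_area_px: int = 30
    eccentricity_threshold: float | None = 1.1
    seed: int = 0

    def __post_init__(self):
        if self.method == "learned" and self.model is None:
            # deferred: the CLI loads the model from disk after construction
            pass
        if self.roi_mode not in ("fixed", "tracking"):
            raise ValueError("roi_mode must be 'fixed' or 'tracking'")


@dataclass
class PipelineResult:
    frames: np.ndarray
    masks: np.ndarray
    poses: list
    roi_origins: list
    track: orientation.PhaseTrack
    speed: kinematics.SpeedSeries
    summary: kinematics.SpeedSummary

    def summary_dict(self) -> dict:
        d = self.summary.as_dict()
        d.update(
            n_frames=int(len(self.frames)),
            n_valid_poses=int(sum(p.valid and p.eccentricity_ok for p in self.poses)),
            n_gap_pairs=len(self.track.gap_pairs),
            fps=self.track.fps,
        )
        return d


def _segmenter_fn(config: PipelineConfig):
    if config.method == "learned":
        if config.model is None:
            raise ValueError("method 'learned' requires a trained model")
        return lambda roi: segmentation.binarize(
            segmentation.predict_mask(config.model, roi), config.binarize_threshold
        )
    if config.method == "kmeans":
        return segmentation.kmeans_segment
    if config.method == "levelset":
        return segmentation.levelset_segment
    if config.method == "threshold":
        return segmentation.threshold_segment
    raise ValueError(f"unknown segmentation method {config.method!r}")


def run_rotation_pipeline(stack: FrameStack, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full per-frame analysis on a frame stack.

    Per frame: extract the ROI, segment the head, keep the largest connected
    component, fit the ellipse, then build the phase track, unwrap it and
    compute the forward-difference angular speed.
    """
    config = config or PipelineConfig()
    frames = stack.frames
    n, h, w = frames.shape
    seg = _segmenter_fn(config)
    center = config.roi_center or ((w - 1) / 2.0, (h - 1) / 2.0)

    if config.roi_mode == "tracking":
        specs = orientation.track_roi(
            frames, center, seg, size=config.roi_size, mode="tracking"
        )
    else:
        specs = [
            orientation.RoiSpec(center=center, size=config.roi_size, mode="fixed")
        ] * n

    masks = np.zeros((n, config.roi_size, config.roi_size), dtype=bool)
    poses, origins = [], []
    n_invalid = 0
    for k in range(n):
        win = orientation.extract_roi(frames[k], specs[k])
        origins.append(win.origin)
        try:
            raw = seg(win.image)
        except ValueError:
            raw = np.zeros_like(win.image, dtype=bool)
        mask, ok = segmentation.postprocess_mask(raw, config.min_area_px)
        masks[k] = mask
        pose = (
            orientation.fit_ellipse(mask, ecc_threshold=config.eccentricity_threshold)
            if ok
            else orientation.EllipsePose()
        )
        if not (pose.valid and pose.eccentricity_ok):
            n_invalid += 1
        poses.append(pose)
    log.info("segmented %d frames (%d without a usable pose)", n, n_invalid)

    track = orientation.phase_signal(poses, fps=config.fps or stack.fps)
    track = orientation.unwrap_phase(track)
    speed = kinematics.angular_speed(track)
    summary = kinematics.summarize_speed(speed)
    log.info(
        "speed: mean %.3f rev/s over %d pairs (%d gaps)",
        summary.mean, summary.n, len(track.gap_pairs),
    )
    return PipelineResult(
        frames=frames, masks=masks, poses=poses, roi_origins=origins,
        track=track, speed=speed, summary=summary,
    )
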