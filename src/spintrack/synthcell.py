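"""Synthetic rotating-cell video generator with exact ground truth.

Emulates the imaging geometry of an optically trapped ellipsoidal cell head
(e.g. a human sperm head: length ~4-5 um, width ~2.5-3.5 um) rotating in the
image plane: a bright filled ellipse, blurred by a Gaussian point-spread
surrogate, over a background carrying smooth bright blobs (out-of-focus
debris under a high-NA objective) and additive Gaussian noise.  The truth
mask is the *unblurred* rasterised ellipse and the truth orientation advances
deterministically, so every downstream stage (segmentation, ellipse fitting,
phase unwrapping, speed estimation) can be scored against exact ground truth.

Conventions
-----------
* Images are float in [0, 1], bright cell on darker background; origin at the
  top-left, rows increase downward.
* The orientation ``alpha`` is the angle of the ellipse major axis in degrees,
  measured counterclockwise from the +x (column) axis in the mathematical
  sense applied to (col, -row); it lives in [0, 180) because an axis has no
  head or tail.
* All randomness is a pure function of ``SynthParams`` (including its seed):
  identical parameters give bit-identical output, and ``render_frame`` for
  frame ``t`` never depends on how many other frames were rendered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter


@dataclass(frozen=True)
class NoiseModel:
    """Background model: additive Gaussian noise plus smooth bright blobs.

    The blobs emulate out-of-focus debris under a high-NA objective and are
    deliberately bright enough to overlap the cell's intensity range, so that
    intensity-only segmentation cannot separate them from the cell — the
    regime in which learned segmentation earns its keep.
    """

    gaussian_sd: float = 0.05
    blob_count: int = 10
    blob_intensity: float = 0.55


@dataclass(frozen=True)
class SynthParams:
    """Geometry, motion and imaging parameters of one synthetic sequence.

    Defaults are the trapped-cell study conditions: head 4.5 x 3.0 um at
    0.1 um/px, recorded at 163 fps in a 150 x 150 px field.
    """

    head_length_um: float = 4.5
    head_width_um: float = 3.0
    pixel_size_um: float = 0.1
    omega_true: float = 2.0        # revolutions per second, in-plane
    fps: float = 163.0
    frame_size: tuple[int, int] = (150, 150)   # (rows, cols)
    center_jitter_px: float = 0.0  # SD of the per-frame Brownian step
    background_noise: NoiseModel = field(default_factory=NoiseModel)
    psf_sigma_px: float = 1.0
    contrast: float = 0.6
    background_level: float = 0.15
    alpha0_deg: float | None = None  # None: drawn uniformly from [0,180)
    alpha_noise_sd_deg: float = 0.0  # optional jitter on alpha; truth records it
    seed: int = 0

    def __post_init__(self):
        if not (self.head_length_um > self.head_width_um > 0):
            raise ValueError("need head_length_um > head_width_um > 0 (a proper ellipse)")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if min(self.frame_size) < 32:
            raise ValueError("frame_size must be >= 32 in both dimensions")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.center_jitter_px < 0 or self.psf_sigma_px < 0:
            raise ValueError("center_jitter_px and psf_sigma_px must be >= 0")
        ax = self.head_length_um / self.pixel_size_um
        if ax > min(self.frame_size):
            raise ValueError(
                f"ellipse major axis {ax:.0f} px exceeds frame size {self.frame_size}"
            )

    @property
    def semi_axes_px(self) -> tuple[float, float]:
        return (
            0.5 * self.head_length_um / self.pixel_size_um,
            0.5 * self.head_width_um / self.pixel_size_um,
        )


@dataclass
class GroundTruth:
    """Per-frame truth: rasterised masks, orientations (deg, [0,180)), centers."""

    masks: np.ndarray        # (n, H, W) bool
    alpha_true: np.ndarray   # (n,) degrees in [0, 180)
    center_true: np.ndarray  # (n, 2) as (cx=col, cy=row)


def _rng_for(params: SynthParams, *key: int) -> np.random.Generator:
    """Independent stream keyed on (seed, key...) so frames are order-free."""
    return np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=tuple(key)))


def _alpha0(params: SynthParams) -> float:
    if params.alpha0_deg is not None:
        return params.alpha0_deg % 180.0
    return float(_rng_for(params, 1).uniform(0.0, 180.0))


def _alpha_true(params: SynthParams, t: int) -> float:
    a = _alpha0(params) + t * params.omega_true * 360.0 / params.fps
    if params.alpha_noise_sd_deg > 0:
        a += float(_rng_for(params, 4, t).normal(0.0, params.alpha_noise_sd_deg))
    return a % 180.0


def _center_true(params: SynthParams, t: int) -> np.ndarray:
    c0 = np.array([(params.frame_size[1] - 1) / 2.0, (params.frame_size[0] - 1) / 2.0])
    if params.center_jitter_px > 0 and t > 0:
        steps = _rng_for(params, 2).normal(0.0, params.center_jitter_px, size=(t, 2))
        c0 = c0 + steps.sum(axis=0)
    return c0


def rasterize_ellipse(
    shape: tuple[int, int], center: np.ndarray, a: float, b: float, alpha_deg: float
) -> np.ndarray:
    """Center-of-pixel inclusion test against the implicit ellipse equation.

    ``center`` is (cx=col, cy=row); ``alpha_deg`` follows the package angle
    convention (CCW from +col axis with y pointing up, i.e. -row).
    """
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx = cols - center[0]
    dy = -(rows - center[1])  # y up
    th = np.deg2rad(alpha_deg)
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _blob_background(params: SynthParams, rng_static: np.random.Generator) -> np.ndarray:
    """Static smooth bright blobs (per-sequence debris), drawn once per seed."""
    h, w = params.frame_size
    bg = np.zeros((h, w))
    nm = params.background_noise
    for _ in range(nm.blob_count):
        r, c = rng_static.uniform(0, h), rng_static.uniform(0, w)
        sig = rng_static.uniform(2.0, 8.0)
        amp = rng_static.uniform(0.3, 1.0) * nm.blob_intensity
        rows, cols = np.mgrid[0:h, 0:w]
        bg += amp * np.exp(-((rows - r) ** 2 + (cols - c) ** 2) / (2 * sig**2))
    return bg


def render_frame(params: SynthParams, t: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Render frame ``t``; returns (frame float [0,1], truth mask bool, truth alpha deg)."""
    if t < 0:
        raise ValueError("frame index t must be >= 0")
    a, b = params.semi_axes_px
    alpha = _alpha_true(params, t)
    center = _center_true(params, t)
    mask = rasterize_ellipse(params.frame_size, center, a, b, alpha)

    img = params.background_level + params.contrast * mask.astype(float)
    if params.psf_sigma_px > 0:
        img = gaussian_filter(img, params.psf_sigma_px)
    img = img + _blob_background(params, _rng_for(params, 0))
    nm = params.background_noise
    if nm.gaussian_sd > 0:
        img = img + _rng_for(params, 3, t).normal(0.0, nm.gaussian_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask, alpha


def generate_sequence(params: SynthParams, n_frames: int):
    """Render ``n_frames`` frames plus aligned :class:`GroundTruth`.

    Returns (frames (n,H,W) float64 in [0,1], GroundTruth).  Raises for
    n_frames < 2 — no speed is computable from a single frame.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2 (no speed from one frame)")
    frames = np.empty((n_frames, *params.frame_size))
    masks = np.empty((n_frames, *params.frame_size), dtype=bool)
    alphas = np.empty(n_frames)
    centers = np.empty((n_frames, 2))
    for t in range(n_frames):
        frames[t], masks[t], alphas[t] = render_frame(params, t)
        centers[t] = _center_true(params, t)
    return frames, GroundTruth(masks=masks, alpha_true=alphas, center_true=centers)


@dataclass(frozen=True)
class TrainingRanges:
    """Sampling ranges for independent single-frame training images."""

    head_length_um: tuple[float, float] = (4.0, 5.0)
    head_width_um: tuple[float, float] = (2.5, 3.5)
    alpha_deg: tuple[float, float] = (0.0, 180.0)
    contrast: tuple[float, float] = (0.4, 0.8)
    center_jitter_px: float = 5.0  # SD of the off-center displacement

    def __post_init__(self):
        for name in ("head_length_um", "head_width_um", "alpha_deg", "contrast"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


def generate_training_set(
    ranges: TrainingRanges | None = None,
    n_images: int = 125,
    seed: int = 0,
    image_size: int = 120,
    template: SynthParams | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw ``n_images`` independent (frame, mask) pairs for supervised training.

    Each pair is a single ``image_size`` x ``image_size`` crop with its exact
    truth mask; orientations are sampled uniformly over the ``alpha_deg``
    range, axes over the configured micron ranges.  Deterministic in ``seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    ranges = ranges or TrainingRanges()
    template = template or SynthParams()
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_images):
        length = rng.uniform(*ranges.head_length_um)
        width = rng.uniform(*ranges.head_width_um)
        alpha = rng.uniform(*ranges.alpha_deg)
        contrast = rng.uniform(*ranges.contrast)
        # keep the whole ellipse inside the crop even when displaced
        max_off = max(0.0, image_size / 2 - length / template.pixel_size_um / 2 - 2)
        off = np.clip(
            rng.normal(0.0, ranges.center_jitter_px, 2), -max_off, max_off
        )
        p = replace(
            template,
            head_length_um=length,
            head_width_um=width,
            alpha0_deg=alpha,
            contrast=contrast,
            omega_true=0.0,
            center_jitter_px=0.0,
            frame_size=(image_size, image_size),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        a, b = p.semi_axes_px
        center = np.array([(image_size - 1) / 2 + off[0], (image_size - 1) / 2 + off[1]])
        mask = rasterize_ellipse(p.frame_size, center, a, b, alpha)
        img = p.background_level + p.contrast * mask.astype(float)
        if p.psf_sigma_px > 0:
            img = gaussian_filter(img, p.psf_sigma_px)
        img = img + _blob_background(p, _rng_for(p, 0))
        if p.background_noise.gaussian_sd > 0:
            img = img + _rng_for(p, 3, 0).normal(0.0, p.background_noise.gaussian_sd, img.shape)
        pairs.append((np.clip(img, 0.0, 1.0), mask))
    return pairs
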