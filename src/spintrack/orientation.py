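"""ROI extraction, ellipse fitting, and orientation-phase tracking.

The head orientation ``alpha`` (degrees, CCW from the +column axis with y
pointing up, defined modulo 180) is extracted per frame by a direct
least-squares conic fit to the outer boundary contour of the binary head mask,
with an image-moments fallback when the conic fit degenerates.  Because an
ellipse axis carries a 180-degree ambiguity, consecutive raw angles are
unwrapped by choosing the smallest-magnitude increment
``((d + 90) mod 180) - 90`` in (-90, 90]; the maximum recoverable rotation
rate is therefore fps/4 revolutions per second.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import EllipseModel, find_contours, regionprops


@dataclass(frozen=True)
class RoiSpec:
    """A square region of interest: fixed (trap-centered) or centroid-tracking."""

    center: tuple[float, float]  # (cx=col, cy=row)
    size: int = 150
    mode: str = "fixed"          # "fixed" | "tracking"

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("ROI size must be >= 32")
        if self.mode not in ("fixed", "tracking"):
            raise ValueError("mode must be 'fixed' or 'tracking'")


@dataclass
class RoiWindow:
    """A cropped ROI plus the bookkeeping needed to map results back."""

    image: np.ndarray
    origin: tuple[int, int]      # (row0, col0) of the crop in the full frame
    padded: bool                 # True when the crop ran off the frame edge


@dataclass
class EllipsePose:
    """Fitted ellipse for one frame; ``alpha`` is trustworthy only when both
    ``valid`` and ``eccentricity_ok`` hold."""

    cx: float = np.nan
    cy: float = np.nan
    a: float = np.nan            # semi-major, px
    b: float = np.nan            # semi-minor, px
    alpha: float = np.nan        # degrees in [0, 180)
    valid: bool = False
    eccentricity_ok: bool = False


@dataclass
class PhaseTrack:
    """Per-frame orientation signal; NaN marks frames with no usable fit."""

    alpha_raw: np.ndarray              # degrees in [0,180), NaN = missing
    frame_indices: np.ndarray
    fps: float
    alpha_unwrapped: np.ndarray | None = None  # cumulative degrees, NaN = missing
    gap_pairs: list = field(default_factory=list)  # (k_prev, k_next) spans over missing frames


def extract_roi(frame: np.ndarray, spec: RoiSpec) -> RoiWindow:
    """Half-open ``size`` x ``size`` crop centered on ``spec.center``,
    zero-padded where it overruns the frame."""
    h, w = frame.shape
    cx, cy = spec.center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"ROI center {spec.center} outside frame {frame.shape}")
    s = spec.size
    r0 = int(round(cy)) - s // 2
    c0 = int(round(cx)) - s // 2
    out = np.zeros((s, s), dtype=frame.dtype)
    rs, re = max(r0, 0), min(r0 + s, h)
    cs, ce = max(c0, 0), min(c0 + s, w)
    out[rs - r0 : re - r0, cs - c0 : ce - c0] = frame[rs:re, cs:ce]
    padded = (rs != r0) or (cs != c0) or (re != r0 + s) or (ce != c0 + s)
    return RoiWindow(image=out, origin=(r0, c0), padded=padded)


def mask_centroid(mask: np.ndarray) -> tuple[float, float] | None:
    """(cx, cy) of the mask foreground, or None for an empty mask."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    return float(cols.mean()), float(rows.mean())


def track_roi(
    frames: np.ndarray,
    initial_center: tuple[float, float],
    mask_provider,
    size: int = 150,
    mode: str = "tracking",
) -> list[RoiSpec]:
    """Per-frame ROI placement.

    In ``tracking`` mode the ROI for frame k+1 is centered on the mask
    centroid of frame k (mapped back to full-frame coordinates), falling back
    to the previous center when frame k yields no mask; ``fixed`` mode keeps
    the initial center throughout.  ``mask_provider(roi_image)`` must return
    a binary mask over the ROI crop.
    """
    n = len(frames)
    specs = []
    center = (float(initial_center[0]), float(initial_center[1]))
    any_valid = False
    for k in range(n):
        specs.append(RoiSpec(center=center, size=size, mode=mode))
        if mode == "fixed" or k == n - 1:
            continue
        win = extract_roi(frames[k], specs[-1])
        cen = mask_centroid(np.asarray(mask_provider(win.image), dtype=bool))
        if cen is not None:
            any_valid = True
            h, w = frames[k].shape
            center = (
                float(np.clip(cen[0] + win.origin[1], 0, w - 1)),
                float(np.clip(cen[1] + win.origin[0], 0, h - 1)),
            )
    if mode == "tracking" and n > 1 and not any_valid:
        raise ValueError("tracking failed: no frame produced a nonempty mask")
    return specs


def fit_ellipse(mask: np.ndarray, min_area: int = 20, ecc_threshold: float | None = 1.1) -> EllipsePose:
    """Fit an ellipse to the outer boundary contour of a binary mask.

    Returns an invalid pose (never raises) when the mask is empty, smaller
    than ``min_area``, has fewer than 5 boundary points, or the conic fit
    degenerates and the moments fallback is unavailable.  Set
    ``ecc_threshold=None`` to trust ``alpha`` regardless of elongation.
    """
    mask = np.asarray(mask).astype(bool)
    area = int(np.count_nonzero(mask))
    if area < max(min_area, 5):
        return EllipsePose()
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        return EllipsePose()
    xy = max(contours, key=len)[:, ::-1]  # (col, row)
    if len(xy) < 5:
        return EllipsePose()

    pose = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = EllipseModel.from_estimate(xy)
    if model:
        xc, yc = model.center
        a, b = model.axis_lengths
        th = model.theta
        if b > a:
            a, b = b, a
            th += np.pi / 2
        if np.isfinite(a) and np.isfinite(b) and b > 0:
            pose = EllipsePose(cx=float(xc), cy=float(yc), a=float(a), b=float(b),
                               alpha=float((-np.degrees(th)) % 180.0), valid=True)
    if pose is None:
        # moments fallback: ellipse with the region's second moments
        rp = regionprops(mask.astype(np.uint8))[0]
        a = rp.axis_major_length / 2.0
        b = rp.axis_minor_length / 2.0
        if b <= 0 or not np.isfinite(a):
            return EllipsePose()
        cy, cx = rp.centroid
        alpha = (90.0 + np.degrees(rp.orientation)) % 180.0
        pose = EllipsePose(cx=float(cx), cy=float(cy), a=float(a), b=float(b),
                           alpha=float(alpha), valid=True)
    pose.eccentricity_ok = ecc_threshold is None or (pose.a / pose.b >= ecc_threshold)
    return pose


def phase_signal(poses: list[EllipsePose], fps: float) -> PhaseTrack:
    """Raw orientation signal; frames with invalid or near-circular fits are
    marked missing (NaN)."""
    if len(poses) < 2:
        raise ValueError("need >= 2 poses")
    alpha = np.array(
        [p.alpha if (p.valid and p.eccentricity_ok) else np.nan for p in poses]
    )
    if np.count_nonzero(~np.isnan(alpha)) < 2:
        raise ValueError("need >= 2 valid poses to form a phase signal")
    return PhaseTrack(alpha_raw=alpha, frame_indices=np.arange(len(poses)), fps=fps)


def wrap_increment(delta_deg):
    """Map an angle difference to the minimal-magnitude representative in (-90, 90].

    A tie at exactly +/-90 degrees resolves to +90 (half-open interval)."""
    return 90.0 - ((90.0 - np.asarray(delta_deg)) % 180.0)


def unwrap_phase(track: PhaseTrack) -> PhaseTrack:
    """Resolve the modulo-180 axis ambiguity into a cumulative phase.

    Each consecutive valid pair advances by the minimal increment in
    (-90, 90]; pairs that span missing frames are recorded in ``gap_pairs``
    (the unwrapped signal continues by the same minimal-increment rule, but
    downstream speed estimation skips those pairs rather than inventing
    rotation across the gap).  Missing frames are never interpolated.
    """
    raw = track.alpha_raw
    unwrapped = np.full_like(raw, np.nan)
    gaps = []
    prev = None
    for k in np.flatnonzero(~np.isnan(raw)):
        if prev is None:
            unwrapped[k] = raw[k]
        else:
            unwrapped[k] = unwrapped[prev] + wrap_increment(raw[k] - unwrapped[prev])
            if k != prev + 1:
                gaps.append((int(prev), int(k)))
        prev = int(k)
    track.alpha_unwrapped = unwrapped
    track.gap_pairs = gaps
    return track
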