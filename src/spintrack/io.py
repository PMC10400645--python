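"""Reading frame stacks, writing pipeline outputs, and the run manifest.

Multi-page TIFF is the canonical interchange format for frames and masks;
numbered PNG/TIFF directories are accepted on input (natural sort order, so
``frame_2`` precedes ``frame_10``).  Tracks and speeds are written as CSV,
summaries and manifests as JSON, so every output is human-checkable and
diff-able.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
from skimage.draw import ellipse_perimeter


@dataclass
class FrameStack:
    """Time-ordered grayscale frames in [0, 1] with their recording rate."""

    frames: np.ndarray          # (n, H, W) float
    fps: float
    pixel_size_um: float | None = None
    source: str | None = None

    def __len__(self) -> int:
        return len(self.frames)


_NUM = re.compile(r"(\d+)")


def natural_key(name: str):
    """Sort key treating digit runs numerically: frame_2 < frame_10."""
    return [int(tok) if tok.isdigit() else tok.lower() for tok in _NUM.split(name)]


def _to_unit_float(img: np.ndarray) -> np.ndarray:
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / np.iinfo(img.dtype).max
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def read_framestack(path, fps: float, pixel_size_um: float | None = None) -> FrameStack:
    """Load a multi-page TIFF or a directory of numbered PNG/TIFF frames.

    Integer pixel values are scaled by their dtype's full range to [0, 1];
    frames of mixed sizes are rejected.
    """
    path = Path(path)
    if fps <= 0:
        raise ValueError("fps must be > 0")
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")),
            key=lambda p: natural_key(p.name),
        )
        if not files:
            raise ValueError(f"no PNG/TIFF frames found in {path}")
        frames = []
        for f in files:
            try:
                img = iio.imread(f)
            except Exception as exc:
                raise ValueError(f"unreadable frame {f}: {exc}") from exc
            if img.ndim == 3:
                img = img.mean(axis=-1)  # RGB -> gray
            frames.append(_to_unit_float(img))
        shapes = {fr.shape for fr in frames}
        if len(shapes) > 1:
            raise ValueError(f"mixed frame sizes in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        try:
            stack = tifffile.imread(path)
        except Exception as exc:
            raise ValueError(f"unreadable file {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 4:
            stack = stack.mean(axis=-1)
        stack = _to_unit_float(stack)
    return FrameStack(frames=stack, fps=fps, pixel_size_um=pixel_size_um, source=str(path))


def write_mask_stack(masks: np.ndarray, path) -> None:
    """Binary masks as a 0/255 uint8 multi-page TIFF."""
    tifffile.imwrite(path, (np.asarray(masks, bool).astype(np.uint8) * 255))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _overlay_stack(frames: np.ndarray, poses, origins) -> np.ndarray:
    """RGB previews with the fitted ellipse perimeter drawn in green."""
    n, h, w = frames.shape
    rgb = np.repeat((np.clip(frames, 0, 1) * 255).astype(np.uint8)[..., None], 3, axis=-1)
    for k, pose in enumerate(poses):
        if not pose.valid:
            continue
        r0, c0 = origins[k] if origins is not None else (0, 0)
        # the stored alpha is CCW with y up; ellipse_perimeter rotates in (row, col)
        rr, cc = ellipse_perimeter(
            int(round(pose.cy + r0)), int(round(pose.cx + c0)),
            int(round(pose.b)), int(round(pose.a)),
            orientation=-np.deg2rad(pose.alpha), shape=(h, w),
        )
        rgb[k, rr, cc] = (0, 255, 0)
    return rgb


def phase_to_frame(track) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": track.frame_indices,
            "alpha_raw_deg": track.alpha_raw,
            "alpha_unwrapped_deg": (
                track.alpha_unwrapped
                if track.alpha_unwrapped is not None
                else np.full_like(track.alpha_raw, np.nan)
            ),
            "valid": (~np.isnan(track.alpha_raw)).astype(int),
        }
    )


def speed_to_frame(series) -> pd.DataFrame:
    return pd.DataFrame(
        {"pair_start_frame": series.pair_indices[:, 0], "omega_rev_s": series.omega}
    )


def write_outputs(result, out_dir) -> dict:
    """Write the full artifact set for one pipeline run; returns the manifest.

    Artifacts: masks.tif, overlays.tif, phase.csv, speed.csv, summary.json —
    plus manifest.json listing each file with its SHA-256 checksum.
    Fails before writing anything when the results are empty or the directory
    cannot be created.
    """
    if result is None or len(result.masks) == 0:
        raise ValueError("empty results: nothing to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    write_mask_stack(result.masks, out / "masks.tif")
    tifffile.imwrite(
        out / "overlays.tif", _overlay_stack(result.frames, result.poses, result.roi_origins)
    )
    phase_to_frame(result.track).to_csv(out / "phase.csv", index=False, float_format="%.6f")
    speed_to_frame(result.speed).to_csv(out / "speed.csv", index=False, float_format="%.6f")
    (out / "summary.json").write_text(json.dumps(result.summary_dict(), indent=2) + "\n")

    manifest = {
        "artifacts": [
            {"file": name, "sha256": _sha256(out / name)}
            for name in ("masks.tif", "overlays.tif", "phase.csv", "speed.csv", "summary.json")
        ]
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def write_synth_outputs(frames: np.ndarray, truth, fps: float, out_dir) -> dict:
    """Write a synthetic sequence: frames.tif, masks.tif, truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "frames.tif", (np.clip(frames, 0, 1) * 65535).astype(np.uint16))
    write_mask_stack(truth.masks, out / "masks.tif")
    pd.DataFrame(
        {
            "frame": np.arange(len(frames)),
            "alpha_deg": truth.alpha_true,
            "cx": truth.center_true[:, 0],
            "cy": truth.center_true[:, 1],
        }
    ).to_csv(out / "truth.csv", index=False, float_format="%.6f")
    return {"frames": str(out / "frames.tif"), "masks": str(out / "masks.tif"),
            "truth": str(out / "truth.csv"), "fps": fps}
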