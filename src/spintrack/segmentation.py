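"""Head segmentation: the learned nested encoder-decoder plus classical baselines.

The learned segmenter is a depth-4 (by default) U-Net++-style network trained
with the hybrid cross-entropy / soft-Dice loss on (frame, mask) pairs; see
:mod:`spintrack.nn`.  Classical comparators — two-cluster intensity k-means,
a Chan-Vese level set, and plain Otsu thresholding — are provided for
benchmarking: on clean images they do well, but blob-structured background
noise degrades them much faster than the trained network, which is the point
the benchmark harness quantifies.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.segmentation import chan_vese

from .metrics import iou
from .nn import Adam, NestedUNet, hybrid_loss, hybrid_loss_grad, one_hot


@dataclass
class TrainConfig:
    """Training hyper-parameters for the learned segmenter.

    ``cv_folds >= 2`` requests k-fold cross-validation (per-fold held-out IoU
    plus a final model retrained on all data with the best epoch count);
    ``cv_folds in (0, 1)`` trains once with a single ``val_fraction`` split.
    """

    depth: int = 4
    base_channels: int = 4
    epochs: int = 20
    learning_rate: float = 5e-3
    batch_size: int = 8
    cv_folds: int = 0
    val_fraction: float = 0.2
    seed: int = 0
    binarize_threshold: float = 0.5
    dice_mode: str = "pixel"       # "pixel" (as printed) or "aggregated"
    augment: bool = True           # random 90-degree rotations and flips
    deep_supervision: bool = False

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 < self.binarize_threshold < 1):
            raise ValueError("binarize_threshold must be in (0, 1)")
        if self.cv_folds < 0:
            raise ValueError("cv_folds must be >= 0")


@dataclass
class CVReport:
    """Held-out performance gathered during training."""

    fold_ious: list = field(default_factory=list)    # per-fold (or single-split) mean IoU
    best_epochs: list = field(default_factory=list)
    epochs_used: int = 0
    history: list = field(default_factory=list)      # (epoch, train_loss, val_iou) triples

    @property
    def mean_iou(self) -> float:
        return float(np.mean(self.fold_ious)) if self.fold_ious else float("nan")


class TrainedSegmenter:
    """A trained network plus the config needed to reproduce its preprocessing."""

    def __init__(self, net: NestedUNet, config: TrainConfig):
        self.net = net
        self.config = config

    def save(self, path) -> None:
        arrays = self.net.state_arrays()
        np.savez(path, _config=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedSegmenter":
        with np.load(path, allow_pickle=False) as data:
            config = TrainConfig(**json.loads(str(data["_config"])))
            net = build_segmenter(config)
            net.load_state_arrays({k: data[k] for k in data.files if k != "_config"})
        return cls(net, config)


def build_segmenter(config: TrainConfig, in_channels: int = 1) -> NestedUNet:
    """Instantiate the nested encoder-decoder for the given config."""
    return NestedUNet(
        in_channels=in_channels,
        depth=config.depth,
        base_channels=config.base_channels,
        seed=config.seed,
        deep_supervision=config.deep_supervision,
    )


# ---------------------------------------------------------------------------
# training


def _to_batches(pairs):
    x = np.stack([np.asarray(f, dtype=np.float32) for f, _ in pairs])[:, None]
    y = np.stack([one_hot(np.asarray(m, dtype=bool)) for _, m in pairs])
    return x, y


def _augment(xb, yb, rng):
    xb, yb = xb.copy(), yb.copy()
    for i in range(len(xb)):
        k = int(rng.integers(0, 4))
        if k:
            xb[i] = np.rot90(xb[i], k, axes=(1, 2))
            yb[i] = np.rot90(yb[i], k, axes=(1, 2))
        if rng.integers(0, 2):
            xb[i] = xb[i, :, :, ::-1]
            yb[i] = yb[i, :, :, ::-1]
    return np.ascontiguousarray(xb), np.ascontiguousarray(yb)


def _heldout_iou(model, x, y, threshold):
    scores = []
    for i in range(0, len(x), 8):
        p = model.forward(x[i : i + 8])
        pred = p[:, 1] >= threshold
        truth = y[i : i + 8, 1] > 0.5
        scores += [iou(pred[j], truth[j]) for j in range(len(pred))]
    return float(np.mean(scores))


def _train_once(x, y, xv, yv, config, rng, report):
    """One training run; returns (net, best_val_iou, best_epoch)."""
    net = build_segmenter(config)
    opt = Adam(net.parameters(), lr=config.learning_rate)
    n = len(x)
    best = (-1.0, 0, None)  # (val_iou, epoch, weights)
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = perm[i : i + config.batch_size]
            xb, yb = x[idx], y[idx]
            if config.augment:
                xb, yb = _augment(xb, yb, rng)
            p = net.forward(xb)
            losses.append(hybrid_loss(p, yb, mode=config.dice_mode))
            net.backward(hybrid_loss_grad(p, yb, mode=config.dice_mode))
            opt.step()
        val_iou = (
            _heldout_iou(net, xv, yv, config.binarize_threshold) if len(xv) else float("nan")
        )
        report.history.append((epoch, float(np.mean(losses)), val_iou))
        if len(xv) and val_iou > best[0]:
            best = (val_iou, epoch, copy.deepcopy(net.state_arrays()))
    if best[2] is not None:
        net.load_state_arrays(best[2])
        return net, best[0], best[1]
    return net, float("nan"), config.epochs


def train_segmenter(dataset, config: TrainConfig | None = None):
    """Train the learned segmenter on (frame, mask) pairs.

    Returns ``(TrainedSegmenter, CVReport)``.  With ``cv_folds >= 2`` the
    dataset is split into folds (reproducible under ``config.seed``), each
    fold's held-out mean IoU is recorded, and the returned model is retrained
    on all data for the median best epoch count; otherwise a single
    ``val_fraction`` split is used and the best-validation-epoch weights are
    returned directly.
    """
    config = config or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    shapes = {(np.asarray(f).shape, np.asarray(m).shape) for f, m in dataset}
    for fs, ms in shapes:
        if fs != ms:
            raise ValueError(f"frame/mask size mismatch: {fs} vs {ms}")
    if config.cv_folds >= 2 and len(dataset) < config.cv_folds:
        raise ValueError(f"need >= {config.cv_folds} samples for {config.cv_folds}-fold CV")

    x, y = _to_batches(dataset)
    rng = np.random.default_rng(config.seed)
    report = CVReport()

    if config.cv_folds >= 2:
        perm = rng.permutation(len(x))
        folds = np.array_split(perm, config.cv_folds)
        for f, hold in enumerate(folds):
            train_idx = np.setdiff1d(perm, hold)
            fold_rng = np.random.default_rng([config.seed, f])
            _, val_iou, best_ep = _train_once(
                x[train_idx], y[train_idx], x[hold], y[hold], config, fold_rng, report
            )
            report.fold_ious.append(val_iou)
            report.best_epochs.append(best_ep)
        epochs_final = int(np.median(report.best_epochs))
        final_cfg = copy.deepcopy(config)
        final_cfg.epochs = max(1, epochs_final)
        net, _, _ = _train_once(
            x, y, x[:0], y[:0], final_cfg, np.random.default_rng([config.seed, 999]), report
        )
        report.epochs_used = final_cfg.epochs
        return TrainedSegmenter(net, config), report

    n_val = max(1, int(round(config.val_fraction * len(x)))) if len(x) > 1 else 0
    perm = rng.permutation(len(x))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    net, val_iou, best_ep = _train_once(
        x[train_idx], y[train_idx], x[val_idx], y[val_idx], config, rng, report
    )
    if n_val:
        report.fold_ious.append(val_iou)
        report.best_epochs.append(best_ep)
    report.epochs_used = best_ep
    return TrainedSegmenter(net, config), report


# ---------------------------------------------------------------------------
# inference


def predict_mask(model: TrainedSegmenter | NestedUNet, frame: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities (2, H, W) for one grayscale frame.

    Frames whose size is not divisible by the network's downsampling factor
    are edge-padded internally and the map is cropped back.
    """
    net = model.net if isinstance(model, TrainedSegmenter) else model
    frame = np.asarray(frame, dtype=np.float32)
    if frame.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale frame, got shape {frame.shape}")
    h, w = frame.shape
    div = 2 ** (net.depth - 1)
    ph = (-h) % div
    pw = (-w) % div
    x = np.pad(frame, ((0, ph), (0, pw)), mode="edge")[None, None]
    p = net.forward(x)[0]
    return p[:, :h, :w]


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Mask = pixels whose cell-class probability is >= threshold (inclusive).

    Accepts a (2, H, W) probability map (channel 1 = cell) or a single-channel
    cell-probability image; idempotent on already-binary input with the
    default threshold.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(prob_map)
    p_cell = p[1] if p.ndim == 3 else p
    return p_cell >= threshold


def postprocess_mask(mask: np.ndarray, min_area_px: int = 20) -> tuple[np.ndarray, bool]:
    """Keep only the largest 8-connected component.

    Returns ``(mask, ok)``; ``ok`` is False (and the mask empty) when the
    largest component is smaller than ``min_area_px``.  Idempotent.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return np.zeros_like(mask), False
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_area_px:
        return np.zeros_like(mask), False
    return labels == largest, True


# ---------------------------------------------------------------------------
# classical baselines


def threshold_segment(frame: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Global intensity threshold (Otsu when ``threshold`` is None)."""
    frame = np.asarray(frame, dtype=float)
    if threshold is None:
        if np.ptp(frame) == 0:
            raise ValueError("cannot threshold a constant frame")
        threshold = threshold_otsu(frame)
    return frame >= threshold


def kmeans_segment(frame: np.ndarray, n_clusters: int = 2, max_iter: int = 100) -> np.ndarray:
    """Two-cluster 1-D intensity k-means with deterministic min/max init.

    The higher-mean cluster is the cell.  Raises on a constant frame.
    """
    if n_clusters != 2:
        raise ValueError("only n_clusters=2 is supported")
    frame = np.asarray(frame, dtype=float)
    v = frame.ravel()
    if v.min() == v.max():
        raise ValueError("constant frame: k-means clustering is undefined")
    lo, hi = float(v.min()), float(v.max())
    for _ in range(max_iter):
        assign = np.abs(v - hi) < np.abs(v - lo)  # True -> bright cluster
        new_lo = v[~assign].mean() if (~assign).any() else lo
        new_hi = v[assign].mean() if assign.any() else hi
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    return (np.abs(frame - hi) < np.abs(frame - lo))


def levelset_segment(frame: np.ndarray, iterations: int = 100, smoothing: float = 0.1) -> np.ndarray:
    """Region-based active contour (Chan-Vese), initialised from a centered box.

    Non-convergence is not an error: the last iterate is returned (Chan-Vese
    runs a fixed iteration budget).  The region with the higher mean intensity
    is reported as the cell.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    init = np.zeros((h, w))
    init[h // 4 : -h // 4 or None, w // 4 : -w // 4 or None] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seg = chan_vese(
            frame, mu=smoothing, max_num_iter=iterations, init_level_set=init, tol=1e-4
        )
    seg = np.asarray(seg, dtype=bool)
    if not seg.any() or seg.all():
        return seg
    if frame[seg].mean() < frame[~seg].mean():
        seg = ~seg
    return seg
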