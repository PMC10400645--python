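"""Hybrid cross-entropy / soft-Dice training criterion.

The per-pixel ("pixel") form is

    L(Y, P) = -(1/N) * sum_c sum_n [ y_nc * log(p_nc) + 2 * (2 y_nc p_nc) / (y_nc^2 + p_nc^2) ]

with N the number of pixels in the batch, y one-hot targets and p softmax
probabilities over C = 2 classes.  The log is clamped at log(eps) and the Dice
fraction is defined as 0 whenever its denominator falls below eps, so the
all-background class contributes nothing.  The minimum is -2, attained exactly
when P = Y: the cross-entropy part vanishes and the Dice reward saturates at 2
for the true class of every pixel.

An image-aggregated variant ("aggregated") replaces the per-pixel Dice
fraction with the classical soft Dice per class over the whole batch,

    L = -(1/N) * sum_{c,n} y_nc log(p_nc) - (2/C) * sum_c (2 sum_n y_nc p_nc) / (sum_n y_nc^2 + sum_n p_nc^2),

normalised so that a perfect prediction again gives -2.
"""

from __future__ import annotations

import numpy as np

_MODES = ("pixel", "aggregated")


def _grad_dtype(p) -> np.dtype:
    """Gradients match the prediction's float dtype (float32 in training)."""
    dt = np.asarray(p).dtype
    return dt if np.issubdtype(dt, np.floating) else np.dtype(np.float32)


def _check(p: np.ndarray, y: np.ndarray) -> int:
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: P {p.shape} vs Y {y.shape}")
    if p.ndim < 2:
        raise ValueError("P must have a class axis at position 1")
    # N counts pixels, not pixel*class entries
    return int(p.size // p.shape[1])


def hybrid_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-7, mode: str = "pixel") -> float:
    """Scalar hybrid loss; arrays shaped (B, C, ...) or (N, C) alike."""
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    n = _check(p, y)
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ce = y * np.log(np.maximum(p, eps))
    if mode == "pixel":
        den = y * y + p * p
        frac = np.where(den < eps, 0.0, 2.0 * y * p / np.where(den < eps, 1.0, den))
        return float(-(ce.sum() + 2.0 * frac.sum()) / n)
    c_axis = 1
    axes = tuple(i for i in range(p.ndim) if i != c_axis)
    num = 2.0 * (y * p).sum(axis=axes)
    den = (y * y).sum(axis=axes) + (p * p).sum(axis=axes)
    dice_c = np.where(den < eps, 0.0, num / np.where(den < eps, 1.0, den))
    return float(-ce.sum() / n - 2.0 * dice_c.mean())


def hybrid_loss_grad(
    p: np.ndarray, y: np.ndarray, eps: float = 1e-7, mode: str = "pixel"
) -> np.ndarray:
    """dL/dP of :func:`hybrid_loss`, same shape as P (float32)."""
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    n = _check(p, y)
    p64 = np.asarray(p, dtype=np.float64)
    y64 = np.asarray(y, dtype=np.float64)
    dce = y64 / np.maximum(p64, eps)
    if mode == "pixel":
        den = y64 * y64 + p64 * p64
        ddice = np.where(
            den < eps, 0.0, 2.0 * y64 * (y64 * y64 - p64 * p64) / np.where(den < eps, 1.0, den) ** 2
        )
        g = -(dce + 2.0 * ddice) / n
        return g.astype(_grad_dtype(p))
    c_axis = 1
    axes = tuple(i for i in range(p64.ndim) if i != c_axis)
    num = 2.0 * (y64 * p64).sum(axis=axes)
    den = (y64 * y64).sum(axis=axes) + (p64 * p64).sum(axis=axes)
    shape = [1] * p64.ndim
    shape[c_axis] = p64.shape[c_axis]
    num_b = num.reshape(shape)
    den_b = np.where(den < eps, np.inf, den).reshape(shape)
    # d dice_c / dp = (2 y * den - num * 2p) / den^2, averaged over classes
    ddice = (2.0 * y64 * den_b - num_b * 2.0 * p64) / den_b**2
    g = -dce / n - 2.0 * ddice / p64.shape[c_axis]
    return g.astype(_grad_dtype(p))


def one_hot(mask: np.ndarray) -> np.ndarray:
    """Boolean mask (..., H, W) -> one-hot (..., 2, H, W): class 0 background, 1 cell."""
    m = np.asarray(mask).astype(bool)
    return np.stack([~m, m], axis=-3).astype(np.float32)
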