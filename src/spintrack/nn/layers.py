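"""Minimal NumPy layers with explicit backprop for small segmentation networks.

All tensors are float32 in NCHW order (batch, channel, row, col). Each layer
caches what its backward pass needs; a layer instance must therefore complete
one forward/backward cycle before being reused, which the trainer guarantees.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B, C*k*k, H*W) patch matrix for a stride-1 convolution."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    b, c, _, _ = x.shape
    win = sliding_window_view(x, (k, k), axis=(2, 3))  # (B,C,H,W,k,k)
    h, w = win.shape[2], win.shape[3]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to image layout."""
    b, c, h, w = x_shape
    g = cols.reshape(b, c, k, k, h, w)
    out = np.zeros((b, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + h, j : j + w] += g[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Conv2d:
    """Stride-1, same-padded convolution (k x k), He-initialised."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.k = k
        self.pad = k // 2
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._x_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, _, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        self._cols, self._x_shape = cols, x.shape
        y = self.W @ cols + self.b[:, None]
        return y.reshape(b, -1, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, cout, h, w = gy.shape
        g = gy.reshape(b, cout, h * w)
        self.dW = np.einsum("bij,bkj->ik", g, self._cols, optimize=True)
        self.db = g.sum(axis=(0, 2))
        gcols = self.W.T @ g
        self._cols = None
        return _col2im(gcols, self._x_shape, self.k, self.pad)

    def parameters(self):
        return [(self, "W"), (self, "b")]


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class MaxPool2:
    """2x2 max pooling, stride 2; input height/width must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(b, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._x_shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x_shape
        flat = np.zeros((b, c, h // 2, w // 2, 4), dtype=gy.dtype)
        np.put_along_axis(flat, self._idx[..., None], gy[..., None], axis=-1)
        return (
            flat.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )


def upsample_nearest(x: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x upsampling."""
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample_nearest_backward(gy: np.ndarray) -> np.ndarray:
    b, c, h, w = gy.shape
    return gy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU, the per-node unit of the network."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, rng, dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, rng, dtype)
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.conv1.backward(self.relu1.backward(self.conv2.backward(self.relu2.backward(gy))))

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()
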