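"""Nested encoder-decoder segmentation network (U-Net++ topology).

The decoder grid contains a node X[i,j] for every i + j <= depth - 1, where i
indexes the semantic level (spatial scale H / 2^i) and j the position along
the dense skip pathway.  Node X[i,j] for j >= 1 receives the channel-wise
concatenation of all same-level predecessors X[i,0..j-1] with the 2x-upsampled
X[i+1,j-1]; the grid therefore aggregates features across scales at every
step, which is what distinguishes this topology from a plain U-Net.  A 1x1
convolution on X[0,depth-1] followed by a two-class softmax yields the
per-pixel (background, cell) probabilities.

With ``deep_supervision`` enabled, every top-row node X[0,1..depth-1] gets its
own 1x1 head and the returned probability map is the average of all heads.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, ConvBlock, MaxPool2, upsample_nearest, upsample_nearest_backward


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class NestedUNet:
    """U-Net++ with ``depth`` levels and ``base_channels * 2**i`` channels at level i.

    depth=1 degenerates to a single conv block plus the classification head
    (no pooling, no skip pathways).
    """

    def __init__(
        self,
        in_channels: int = 1,
        depth: int = 4,
        base_channels: int = 8,
        num_classes: int = 2,
        seed: int = 0,
        deep_supervision: bool = False,
        dtype=np.float32,
    ):
        if depth < 1:
            raise ValueError(f"depth must be >= 1, got {depth}")
        if in_channels < 1:
            raise ValueError(f"in_channels must be >= 1, got {in_channels}")
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype)
        self.depth = depth
        self.in_channels = in_channels
        self.num_classes = num_classes
        self.deep_supervision = deep_supervision and depth > 1
        f = [base_channels * 2**i for i in range(depth)]
        self.channels = f

        self.blocks: dict[tuple[int, int], ConvBlock] = {}
        for i in range(depth):
            cin = in_channels if i == 0 else f[i - 1]
            self.blocks[(i, 0)] = ConvBlock(cin, f[i], rng, dtype)
        for j in range(1, depth):
            for i in range(depth - j):
                cin = j * f[i] + f[i + 1]
                self.blocks[(i, j)] = ConvBlock(cin, f[i], rng, dtype)

        n_heads = depth - 1 if self.deep_supervision else 1
        self.heads = [Conv2d(f[0], num_classes, 1, rng, dtype) for _ in range(n_heads)]
        self.pools = {i: MaxPool2() for i in range(1, depth)}
        self._X: dict[tuple[int, int], np.ndarray] = {}
        self._probs: np.ndarray | None = None

    # -- forward ----------------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return per-pixel class probabilities, shape (B, num_classes, H, W).

        H and W must be divisible by 2**(depth-1).
        """
        d = self.depth
        div = 2 ** (d - 1)
        if x.ndim != 4 or x.shape[1] != self.in_channels:
            raise ValueError(f"expected (B,{self.in_channels},H,W) input, got {x.shape}")
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(f"spatial dims must be divisible by {div}, got {x.shape[2:]}")
        x = np.ascontiguousarray(x, dtype=self.dtype)
        X = self._X = {}
        for i in range(d):
            inp = x if i == 0 else self.pools[i].forward(X[(i - 1, 0)])
            X[(i, 0)] = self.blocks[(i, 0)].forward(inp)
        for j in range(1, d):
            for i in range(d - j):
                up = upsample_nearest(X[(i + 1, j - 1)])
                inp = np.concatenate([X[(i, jj)] for jj in range(j)] + [up], axis=1)
                X[(i, j)] = self.blocks[(i, j)].forward(inp)

        if self.deep_supervision:
            self._head_probs = [
                softmax_channels(h.forward(X[(0, j + 1)])) for j, h in enumerate(self.heads)
            ]
            probs = np.mean(self._head_probs, axis=0)
        else:
            probs = softmax_channels(self.heads[0].forward(X[(0, d - 1)]))
        self._probs = probs
        return probs

    # -- backward ---------------------------------------------------------

    def backward(self, dprobs: np.ndarray) -> None:
        """Accumulate parameter gradients from dL/dprobs of the last forward."""
        d = self.depth
        gX: dict[tuple[int, int], np.ndarray] = {}

        def _add(key, g):
            gX[key] = g if key not in gX else gX[key] + g

        if self.deep_supervision:
            # the output is the mean of the per-head softmaxes, so each head
            # receives 1/n_heads of the upstream gradient through its own softmax
            dp = dprobs / len(self.heads)
            for j, (head, ph) in enumerate(zip(self.heads, self._head_probs)):
                dlog = ph * (dp - (ph * dp).sum(axis=1, keepdims=True))
                _add((0, j + 1), head.backward(dlog))
        else:
            p = self._probs
            dlogits = p * (dprobs - (p * dprobs).sum(axis=1, keepdims=True))
            _add((0, d - 1), self.heads[0].backward(dlogits))

        f = self.channels
        for j in range(d - 1, 0, -1):
            for i in range(d - j):
                if (i, j) not in gX:
                    continue
                gin = self.blocks[(i, j)].backward(gX[(i, j)])
                # split the concat: j same-level parts of f[i] channels, then f[i+1]
                ofs = 0
                for jj in range(j):
                    _add((i, jj), gin[:, ofs : ofs + f[i]])
                    ofs += f[i]
                _add((i + 1, j - 1), upsample_nearest_backward(gin[:, ofs:]))
        for i in range(d - 1, -1, -1):
            gin = self.blocks[(i, 0)].backward(gX[(i, 0)])
            if i > 0:
                _add((i - 1, 0), self.pools[i].backward(gin))
        self._X = {}

    # -- parameters -------------------------------------------------------

    def parameters(self) -> list:
        params = []
        for key in sorted(self.blocks):
            params += self.blocks[key].parameters()
        for h in self.heads:
            params += h.parameters()
        return params

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {f"p{i}": getattr(obj, name) for i, (obj, name) in enumerate(self.parameters())}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (obj, name) in enumerate(self.parameters()):
            cur = getattr(obj, name)
            new = np.asarray(arrays[f"p{i}"], dtype=cur.dtype)
            if new.shape != cur.shape:
                raise ValueError(f"parameter {i} shape mismatch: {new.shape} vs {cur.shape}")
            setattr(obj, name, new)

    @property
    def n_nodes(self) -> int:
        """Number of grid nodes X[i,j]; equals depth*(depth-1)/2 + depth."""
        return len(self.blocks)
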