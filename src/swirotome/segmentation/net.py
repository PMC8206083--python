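"""Minimal seeded encoder-decoder convnet on numpy.

Implements exactly what the two-class ROI segmenter needs: 3x3 same-padding
convolutions (im2col + BLAS matmul), ReLU, 2x max pooling, 2x nearest
upsampling, a 1x1 classification head, per-pixel softmax cross-entropy and
SGD with momentum.  Single-threaded determinism: every weight is drawn from
one seeded Generator and updates are plain dense arithmetic.
"""

from __future__ import annotations

import numpy as np


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches for a same-padded 3x3 conv."""
    n, c, h, w = x.shape
    p = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    v = np.lib.stride_tricks.sliding_window_view(p, (3, 3), axis=(2, 3))
    cols = v.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * 9)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Conv3x3:
    """3x3 convolution, stride 1, same padding."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 9))
        self.w = rng.normal(0.0, scale, (cout, cin * 9)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        y = cols @ self.w.T + self.b
        if train:
            self._cols, self._shape = cols, (n, c, h, w)
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dmat = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout).astype(np.float32)
        self.gw = dmat.T @ self._cols
        self.gb = dmat.sum(axis=0)
        # dx = same-conv of dy with spatially flipped, channel-swapped kernels
        wk = self.w.reshape(self.cout, self.cin, 3, 3)[:, :, ::-1, ::-1]
        wb = wk.transpose(1, 0, 2, 3).reshape(self.cin, self.cout * 9)
        dx = _im2col3(dy) @ wb.T
        self._cols = None
        return dx.reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)

    def step(self, lr: float, momentum: float) -> None:
        self.vw = momentum * self.vw - lr * self.gw
        self.vb = momentum * self.vb - lr * self.gb
        self.w += self.vw
        self.b += self.vb


class Conv1x1(Conv3x3):
    """1x1 convolution head."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / cin)
        self.w = rng.normal(0.0, scale, (cout, cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.vw = np.zeros_like(self.w)
        self.vb = np.zeros_like(self.b)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(-1, c)
        y = flat @ self.w.T + self.b
        if train:
            self._flat, self._shape = flat, (n, c, h, w)
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dmat = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout).astype(np.float32)
        self.gw = dmat.T @ self._flat
        self.gb = dmat.sum(axis=0)
        dx = dmat @ self.w
        self._flat = None
        return dx.reshape(n, h, w, c).transpose(0, 3, 1, 2)


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._pos = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos

    def step(self, lr: float, momentum: float) -> None:
        pass


class MaxPool2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            mask = xr == y[:, :, :, None, :, None]
            count = mask.sum(axis=(3, 5), keepdims=True)
            self._mask = mask / count
            self._shape = (n, c, h, w)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d = self._mask * dy[:, :, :, None, :, None]
        self._mask = None
        return d.reshape(n, c, h, w)

    def step(self, lr: float, momentum: float) -> None:
        pass


class Upsample2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))

    def step(self, lr: float, momentum: float) -> None:
        pass


class SegNet:
    """Two-class encoder-decoder with ``depth`` down/up-sampling stages."""

    def __init__(
        self,
        in_channels: int = 1,
        n_classes: int = 2,
        depth: int = 3,
        base_width: int = 16,
        seed: int = 0,
    ):
        if depth < 1:
            raise ValueError("depth must be >= 1")
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_width = base_width
        self.in_channels = in_channels
        self.n_classes = n_classes
        layers: list = []
        c = in_channels
        widths = [base_width * 2**i for i in range(depth)]
        for wdt in widths:  # encoder: conv-relu + pool per stage
            layers += [Conv3x3(c, wdt, rng), ReLU(), MaxPool2()]
            c = wdt
        # bottleneck conv at the coarsest resolution
        layers += [Conv3x3(c, c, rng), ReLU()]
        # decoder: conv-relu at the coarse resolution, then 2x upsample;
        # convolving before upsampling keeps the flop count low
        down = list(reversed(widths[:-1])) + [max(base_width // 2, 4)]
        for wdt in down:
            layers += [Conv3x3(c, wdt, rng), ReLU(), Upsample2()]
            c = wdt
        # full-resolution refinement + 1x1 classification head
        layers += [Conv3x3(c, c, rng), ReLU(), Conv1x1(c, n_classes, rng)]
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def step(self, lr: float, momentum: float) -> None:
        for layer in self.layers:
            layer.step(lr, momentum)

    def train_step(
        self, x: np.ndarray, target: np.ndarray, lr: float, momentum: float
    ) -> float:
        """One SGD step on a batch; returns the mean cross-entropy loss."""
        logits = self.forward(x, train=True)
        loss, dlogits = softmax_xent(logits, target)
        self.backward(dlogits)
        self.step(lr, momentum)
        return loss

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class map; the argmax tie goes to class 0 (not-ROI)."""
        logits = self.forward(x, train=False)
        return (logits[:, 1] > logits[:, 0]).astype(np.uint8)

    # -- weights -----------------------------------------------------------
    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Conv3x3):
                out[f"w{i}"] = layer.w
                out[f"b{i}"] = layer.b
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Conv3x3):
                layer.w = weights[f"w{i}"].astype(np.float32)
                layer.b = weights[f"b{i}"].astype(np.float32)


def softmax_xent(logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-pixel softmax cross-entropy and its logits gradient.

    ``logits``: (N, K, H, W); ``target``: (N, H, W) integer class map.
    """
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    p = e / e.sum(axis=1, keepdims=True)
    n, k, h, w = logits.shape
    onehot = np.zeros_like(p)
    grid_n, grid_h, grid_w = np.meshgrid(
        np.arange(n), np.arange(h), np.arange(w), indexing="ij"
    )
    onehot[grid_n, target, grid_h, grid_w] = 1.0
    eps = 1e-12
    loss = float(-(onehot * np.log(p + eps)).sum() / (n * h * w))
    dlogits = (p - onehot) / (n * h * w)
    return loss, dlogits.astype(np.float32)
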