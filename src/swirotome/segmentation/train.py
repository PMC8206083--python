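"""Training and inference for the semantic ROI segmenter.

Frames are resized to the network input shape (bilinear; masks nearest),
augmented with random integer translations, and optimized with SGD +
momentum on per-pixel cross-entropy.  The desk-scale defaults (5 epochs,
base width 16) keep CPU-only runs fast; the reference configuration
(60 epochs) is available via :meth:`SegConfig.reference`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import transform as sktransform

from ..dataio import MAX_COUNT, Frame, ROIMask
from .net import SegNet


@dataclass(frozen=True)
class SegConfig:
    """Segmenter training configuration."""

    input_shape: tuple[int, int] = (128, 160)
    encoder_depth: int = 3
    momentum: float = 0.9
    epochs: int = 6
    augment_px: int = 15  # random translation amplitude, each direction
    validation_fraction: float = 0.20
    batch_size: int = 8
    learning_rate: float = 0.02
    lr_decay: float = 0.3  # multiplier applied over the last third of training
    base_width: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.encoder_depth < 1:
            raise ValueError("encoder_depth must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.augment_px < 0:
            raise ValueError("augment_px must be >= 0")
        div = 2**self.encoder_depth
        if self.input_shape[0] % div or self.input_shape[1] % div:
            raise ValueError(f"input_shape must be divisible by {div}")

    @classmethod
    def reference(cls, **overrides) -> "SegConfig":
        """The full-scale training schedule (60 epochs)."""
        return replace(cls(epochs=60), **overrides)


@dataclass
class SegModel:
    """A trained segmenter plus its configuration and training log."""

    net: SegNet
    config: SegConfig
    log: pd.DataFrame = field(default_factory=pd.DataFrame)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        weights = self.net.get_weights()
        np.savez(
            path,
            __config__=np.frombuffer(
                json.dumps(asdict(self.config)).encode(), dtype=np.uint8
            ),
            **weights,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "SegModel":
        data = np.load(Path(path))
        doc = json.loads(bytes(data["__config__"]).decode())
        doc["input_shape"] = tuple(doc["input_shape"])
        config = SegConfig(**doc)
        net = SegNet(
            in_channels=2,
            depth=config.encoder_depth,
            base_width=config.base_width,
            seed=config.seed,
        )
        net.set_weights({k: data[k] for k in data.files if k != "__config__"})
        return cls(net=net, config=config)

    def save_log(self, path: str | Path) -> Path:
        path = Path(path)
        self.log.to_csv(path, index=False)
        return path


def _input_channels(pixels: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """(2, H, W) network input: scaled intensity + local texture strength.

    The texture channel is measured at native resolution (before any
    resize) so that fine-grained sharpness survives the downsampling.
    """
    img = pixels.astype(np.float32) / MAX_COUNT
    mean = ndimage.uniform_filter(img, size=5)
    sq = ndimage.uniform_filter(img * img, size=5)
    local_std = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    tex = np.clip(local_std * 50.0, 0, 1)
    if img.shape != shape:
        img = sktransform.resize(img, shape, order=1, preserve_range=True,
                                 anti_aliasing=False).astype(np.float32)
        tex = sktransform.resize(tex, shape, order=1, preserve_range=True,
                                 anti_aliasing=False).astype(np.float32)
    return np.stack([img - 0.5, tex - 0.5])


def _prepare(
    frames: Sequence[Frame], masks: Sequence[ROIMask], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.empty((len(frames), 2, *shape), dtype=np.float32)
    ys = np.empty((len(frames), *shape), dtype=np.int64)
    for i, (fr, mk) in enumerate(zip(frames, masks)):
        if fr.shape != mk.shape:
            raise ValueError("frame/mask shape mismatch")
        xs[i] = _input_channels(fr.pixels, shape)
        if fr.shape != shape:
            m = sktransform.resize(mk.mask.astype(float), shape, order=0,
                                   preserve_range=True) > 0.5
        else:
            m = mk.mask
        ys[i] = m.astype(np.int64)
    return xs, ys


def _translate(x: np.ndarray, y: np.ndarray, dr: int, dc: int) -> tuple:
    """Shift image (pad value = background) and mask (pad 0) together."""
    if dr == 0 and dc == 0:
        return x, y
    h, w = y.shape
    xo = np.full_like(x, -0.5)
    yo = np.zeros_like(y)
    rs, re = max(dr, 0), min(h + dr, h)
    cs, ce = max(dc, 0), min(w + dc, w)
    xo[:, rs:re, cs:ce] = x[:, rs - dr : re - dr, cs - dc : ce - dc]
    yo[rs:re, cs:ce] = y[rs - dr : re - dr, cs - dc : ce - dc]
    return xo, yo


def _pixel_accuracy(net: SegNet, xs: np.ndarray, ys: np.ndarray,
                    batch: int = 8) -> float:
    hits = 0
    for i in range(0, len(xs), batch):
        pred = net.predict(xs[i : i + batch])
        hits += int((pred == ys[i : i + batch]).sum())
    return hits / ys.size


def train_segmenter(
    frames: Sequence[Frame],
    masks: Sequence[ROIMask],
    config: SegConfig = SegConfig(),
) -> SegModel:
    """Train the two-class encoder-decoder from random initialization.

    Requires at least 20 frames with aligned {0,1} masks.  Returns the
    model with a per-epoch log of training/validation pixel accuracy.
    """
    if len(frames) < 20:
        raise ValueError("need at least 20 frames to train")
    if len(frames) != len(masks):
        raise ValueError("frames and masks must align")
    xs, ys = _prepare(frames, masks, tuple(config.input_shape))

    rng = np.random.default_rng(config.seed)
    n = len(xs)
    perm = rng.permutation(n)
    n_val = max(int(round(config.validation_fraction * n)), 1)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xt, yt = xs[train_idx], ys[train_idx]
    xv, yv = xs[val_idx], ys[val_idx]

    net = SegNet(in_channels=2, depth=config.encoder_depth,
                 base_width=config.base_width, seed=config.seed)
    log_rows = []
    a = config.augment_px
    for epoch in range(config.epochs):
        lr = config.learning_rate
        if epoch >= config.epochs - max(config.epochs // 3, 1):
            lr *= config.lr_decay
        order = rng.permutation(len(xt))
        losses = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start : start + config.batch_size]
            xb = np.empty_like(xt[sel])
            yb = np.empty_like(yt[sel])
            for j, idx in enumerate(sel):
                dr = int(rng.integers(-a, a + 1)) if a else 0
                dc = int(rng.integers(-a, a + 1)) if a else 0
                xb[j], yb[j] = _translate(xt[idx], yt[idx], dr, dc)
            losses.append(net.train_step(xb, yb, lr, config.momentum))
        log_rows.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "train_acc": _pixel_accuracy(net, xt, yt),
                "val_acc": _pixel_accuracy(net, xv, yv),
            }
        )
    return SegModel(net=net, config=config, log=pd.DataFrame(log_rows))


def predict_mask(model: SegModel, frame: Frame) -> ROIMask:
    """Per-pixel two-class prediction, resized back to the frame's shape."""
    shape = tuple(model.config.input_shape)
    x = _input_channels(frame.pixels, shape)[None]
    pred = model.net.predict(x)[0].astype(bool)
    if frame.shape != shape:
        pred = sktransform.resize(pred.astype(float), frame.shape, order=0,
                                  preserve_range=True) > 0.5
    return ROIMask(pred, provenance="semantic")
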