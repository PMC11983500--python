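"""Convolutional encoders for time-frequency images.

Two families of residual encoders are provided:

* ``resnet18`` / ``resnet34`` — the standard basic-block ResNet topologies
  (stage widths 64/128/256/512, 7x7 stem, max-pool), used as the target and
  source encoders at full scale;
* ``tiny18`` / ``tiny34`` — structurally identical scaled-down variants
  (stage widths 8/16/32/64, light 3x3 stem, one/two blocks per stage) for
  fast experiments on small images.

Every encoder exposes *taps* at the four residual-stage outputs (the feature
maps consumed by the feature-matching network) and can report, per main-path
convolution kernel, the spatial mean of its activation map — the "per-kernel
deep feature" representation.  Main-path kernels exclude the 1x1 shortcut
(downsampling) convolutions; under that convention ResNet-18 has exactly
3,904 kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "EncoderSpec",
    "FeatureMaps",
    "Encoder",
    "build_encoder",
    "forward_with_taps",
    "count_feature_kernels",
    "train_source",
    "fit_encoder",
    "TrainHyper",
]

_VARIANTS = {
    # widths per stage, blocks per stage, stem width, stem style
    "resnet18": dict(widths=(64, 128, 256, 512), blocks=(2, 2, 2, 2), stem=64, deep_stem=True),
    "resnet34": dict(widths=(64, 128, 256, 512), blocks=(3, 4, 6, 3), stem=64, deep_stem=True),
    "tiny18": dict(widths=(8, 16, 32, 64), blocks=(1, 1, 1, 1), stem=8, deep_stem=False),
    "tiny34": dict(widths=(8, 16, 32, 64), blocks=(2, 2, 2, 2), stem=8, deep_stem=False),
}


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture selection for an encoder."""

    variant: str
    in_channels: int
    n_classes: int = 2
    tap_points: tuple = ("stage1", "stage2", "stage3", "stage4")
    seed: int = 0

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown encoder variant: {self.variant!r}")
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    @property
    def stage_widths(self) -> tuple:
        return _VARIANTS[self.variant]["widths"]


@dataclass
class FeatureMaps:
    """Tapped stage outputs of a single forward pass."""

    maps: list  # list of Tensors [B, C, h, w], one per tap
    tap_ids: list

    def __post_init__(self):
        if len(self.maps) != len(self.tap_ids):
            raise ValueError("maps and tap_ids must have equal length")


class _BasicBlock(nn.Module):
    def __init__(self, c_in, c_out, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, stride=1, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down_conv = nn.Conv2d(c_in, c_out, 1, stride=stride, bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(c_out)
        else:
            self.down_conv = None

    def __call__(self, x, sink=None):
        h = nn.relu(self.bn1(self.conv1(x)))
        if sink is not None:
            sink.append(h)
        h2 = self.bn2(self.conv2(h))
        if sink is not None:
            sink.append(h2)
        sc = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(h2 + sc)


class Encoder(nn.Module):
    """Residual encoder with stage taps and per-kernel feature collection."""

    def __init__(self, spec: EncoderSpec):
        super().__init__()
        cfg = _VARIANTS[spec.variant]
        rng = np.random.default_rng(spec.seed)
        self.spec = spec
        self.frozen = False
        if cfg["deep_stem"]:
            self.stem_conv = nn.Conv2d(spec.in_channels, cfg["stem"], 7, stride=2, padding=3, bias=False, rng=rng)
        else:
            self.stem_conv = nn.Conv2d(spec.in_channels, cfg["stem"], 3, stride=1, padding=1, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(cfg["stem"])
        self._deep_stem = cfg["deep_stem"]
        self.stages = []
        c_in = cfg["stem"]
        for si, (w, nb) in enumerate(zip(cfg["widths"], cfg["blocks"])):
            blocks = []
            for bi in range(nb):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(_BasicBlock(c_in, w, stride, rng))
                c_in = w
            self.stages.append(blocks)
        self.head = nn.Linear(cfg["widths"][-1], spec.n_classes, rng=rng)

    # main-path conv activations of the latest forward, when requested
    def forward(self, x: Tensor, collect_kernels: bool = False, want_taps: bool = False):
        sink = [] if collect_kernels else None
        h = nn.relu(self.stem_bn(self.stem_conv(x)))
        if sink is not None:
            sink.append(h)
        if self._deep_stem:
            h = nn.max_pool2d(h, 3, 2, 1)
        taps = []
        for blocks in self.stages:
            for blk in blocks:
                h = blk(h, sink=sink)
            taps.append(h)
        pooled = h.mean(axis=(2, 3))
        logits = self.head(pooled)
        out = [logits]
        if want_taps:
            out.append(FeatureMaps(maps=taps, tap_ids=list(self.spec.tap_points)))
        if collect_kernels:
            out.append(sink)
        return tuple(out) if len(out) > 1 else logits

    def __call__(self, x, **kw):
        return self.forward(x, **kw)

    def weights_hash(self) -> str:
        import hashlib

        hsh = hashlib.sha256()
        for name, p in sorted(self.named_parameters()):
            hsh.update(name.encode())
            hsh.update(np.ascontiguousarray(p.data).tobytes())
        return hsh.hexdigest()


def build_encoder(spec: EncoderSpec) -> Encoder:
    """Instantiate an encoder with deterministic seeded initialization."""
    return Encoder(spec)


def forward_with_taps(enc: Encoder, batch) -> tuple:
    """Run a batch (Tensor or array, NCHW) through the encoder, returning
    ``(logits, FeatureMaps)`` from a single pass."""
    x = batch if isinstance(batch, Tensor) else Tensor(batch)
    expect = enc.spec.in_channels
    if x.shape[1] != expect:
        raise ValueError(f"channel mismatch: encoder expects {expect} input channels, got {x.shape[1]}")
    logits, taps = enc.forward(x, want_taps=True)
    return logits, taps


def count_feature_kernels(spec: EncoderSpec | str) -> int:
    """Number of main-path convolution output channels (stem + two convs per
    basic block); 1x1 shortcut convolutions are not feature extractors and are
    excluded.  This is the length of the per-kernel deep-feature vector."""
    variant = spec if isinstance(spec, str) else spec.variant
    if variant not in _VARIANTS:
        raise ValueError(f"unknown encoder variant: {variant!r}")
    cfg = _VARIANTS[variant]
    return cfg["stem"] + sum(nb * 2 * w for nb, w in zip(cfg["blocks"], cfg["widths"]))


@dataclass
class TrainHyper:
    """Optimization settings for encoder training."""

    epochs: int = 30
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 16
    cosine_decay: bool = True
    seed: int = 0


def _iter_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i : i + batch_size]


def fit_encoder(enc: Encoder, images: np.ndarray, labels: np.ndarray, hyper: TrainHyper,
                extra_params=(), batch_loss_hook=None):
    """Shared mini-batch training loop: cross-entropy plus an optional extra
    loss term supplied by ``batch_loss_hook(x_tensor, idx, taps) -> Tensor | None``,
    where ``taps`` are the stage FeatureMaps of the same forward pass.

    Without a hook the encoder forward skips tap bookkeeping, so a hook-less
    run consumes exactly the same random stream as a hooked one.  Returns a
    history dict with per-epoch mean cross-entropy (and the extra component).
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain at least two classes")
    params = list(enc.parameters()) + list(extra_params)
    opt = nn.SGD(params, lr=hyper.lr, momentum=hyper.momentum)
    rng = np.random.default_rng(hyper.seed)
    history = {"ce": [], "extra": []}
    n = images.shape[0]
    enc.train()
    for epoch in range(hyper.epochs):
        if hyper.cosine_decay and hyper.epochs > 1:
            opt.lr = hyper.lr * 0.5 * (1 + np.cos(np.pi * epoch / (hyper.epochs - 1)))
        ce_sum, ex_sum, nb = 0.0, 0.0, 0
        for idx in _iter_batches(n, hyper.batch_size, rng):
            x = Tensor(images[idx])
            if batch_loss_hook is None:
                logits = enc.forward(x)
                taps = None
            else:
                logits, taps = enc.forward(x, want_taps=True)
            loss = nn.cross_entropy(logits, labels[idx])
            ce_sum += float(loss.data)
            if batch_loss_hook is not None:
                extra = batch_loss_hook(x, idx, taps)
                if extra is not None:
                    ex_sum += float(extra.data)
                    loss = loss + extra
            nb += 1
            opt.zero_grad()
            loss.backward()
            opt.step()
        history["ce"].append(ce_sum / max(nb, 1))
        history["extra"].append(ex_sum / max(nb, 1))
    enc.eval()
    return history


def train_source(enc: Encoder, images: np.ndarray, labels: np.ndarray,
                 hyper: TrainHyper | None = None) -> tuple:
    """Train the source-domain encoder with cross-entropy and freeze it.

    Returns ``(encoder, history)``; the encoder's parameters are marked
    non-trainable afterwards so transfer training cannot modify them.
    """
    hyper = hyper or TrainHyper()
    history = fit_encoder(enc, images, labels, hyper)
    enc.freeze()
    enc.frozen = True
    return enc, history
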