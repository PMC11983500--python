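"""Adaptive feature-matching network for heterogeneous transfer.

Knowledge is distilled from a frozen source encoder into a target encoder
through a weighted feature-matching loss.  For each candidate pairing of a
source residual stage ``k`` with a target stage ``d``:

* a small fully connected *weight network* f_phi^(k,d) maps the spatially
  pooled source feature map to one nonnegative weight per source channel
  (softplus output, normalized to mean 1 per sample) — feature maps the
  source deems important for the target task receive larger weights;
* the source map is bilinearly resized to the target stage's spatial size,
  the target map is passed through a learnable 1x1-convolution channel
  aligner (C_target -> C_source), both are L2-normalized per channel over
  space, and the weighted mean squared distance over source channels forms
  the matching loss.

Transfer training minimizes cross-entropy on the target task plus
``beta`` times the summed matching losses, jointly over the target encoder,
the weight networks and the channel aligners; the source encoder stays
frozen throughout.  Because the source is frozen, its feature maps and
pooled vectors are precomputed once per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .encoders import Encoder, TrainHyper, fit_encoder

__all__ = [
    "WeightNet",
    "MatchPair",
    "TransferHyper",
    "FeatureMatcher",
    "pair_weights",
    "matching_loss",
    "transfer_train",
    "default_candidate_pairs",
    "modality_adapter_matrix",
]

_EPS = 1e-12


@dataclass
class TransferHyper:
    """Hyperparameters of transfer training."""

    beta: float = 0.5
    candidate_pairs: tuple | None = None  # ((source_stage, target_stage), ...), 0-based
    epochs: int = 10
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 16
    cosine_decay: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.candidate_pairs is not None and len(self.candidate_pairs) == 0:
            raise ValueError("candidate_pairs must be nonempty")


def default_candidate_pairs(n_stages: int = 4) -> tuple:
    """All (source stage k, target stage d) with k >= d: coarse-to-fine
    transfer — deeper source stages may feed equal-or-shallower target stages."""
    return tuple((k, d) for k in range(n_stages) for d in range(n_stages) if k >= d)


class WeightNet(nn.Module):
    """Per-pair fully connected network: pooled source map -> per-channel
    nonnegative transfer weights, normalized to mean 1 per sample."""

    def __init__(self, n_channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(4, n_channels // 2)
        self.fc1 = nn.Linear(n_channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, n_channels, rng=rng)
        self.n_channels = n_channels

    def __call__(self, pooled: Tensor) -> Tensor:
        raw = nn.softplus(self.fc2(nn.relu(self.fc1(pooled))))
        mean = raw.mean(axis=1, keepdims=True)
        return raw / (mean + _EPS)


class MatchPair(nn.Module):
    """A candidate source-stage -> target-stage pairing with its learnable
    1x1 channel aligner (target channels -> source channels)."""

    def __init__(self, source_tap: int, target_tap: int, c_source: int, c_target: int,
                 rng: np.random.Generator | None = None, identity_init: bool = False):
        super().__init__()
        self.source_tap = source_tap
        self.target_tap = target_tap
        self.c_source = c_source
        self.c_target = c_target
        self.aligner = nn.Conv2d(c_target, c_source, 1, bias=False, rng=rng or np.random.default_rng(0))
        if identity_init:
            if c_source != c_target:
                raise ValueError("identity_init requires equal channel counts")
            self.aligner.weight.data[:] = np.eye(c_source, dtype=np.float32)[:, :, None, None]


def pair_weights(wn: WeightNet, source_map) -> Tensor:
    """Transfer weights for a batch of source maps [B, C_s, h, w]: spatially
    pool, run the weight network; output is >= 0 with per-sample mean 1."""
    x = source_map if isinstance(source_map, Tensor) else Tensor(np.asarray(source_map, dtype=np.float32))
    if x.shape[1] != wn.n_channels:
        raise ValueError(f"weight net expects {wn.n_channels} channels, got {x.shape[1]}")
    pooled = x.mean(axis=(2, 3))
    return wn(pooled)


def _l2_normalize_maps(x: Tensor) -> Tensor:
    """L2-normalize each (sample, channel) map over its flattened spatial extent."""
    norm = ((x * x).sum(axis=(2, 3), keepdims=True) + _EPS) ** 0.5
    return x / norm


def matching_loss(source_map, target_map, pair: MatchPair, weights) -> Tensor:
    """Weighted feature-matching loss between a source and a target map.

    ``loss = mean_b sum_c w[b,c] * || n(resize(S))[b,c] - n(align(T))[b,c] ||^2 / C_s``
    where n() is per-map L2 normalization.  Zero iff the weighted normalized
    maps coincide.
    """
    s = source_map if isinstance(source_map, Tensor) else Tensor(np.asarray(source_map, dtype=np.float32))
    t = target_map if isinstance(target_map, Tensor) else Tensor(np.asarray(target_map, dtype=np.float32))
    w = weights if isinstance(weights, Tensor) else Tensor(np.asarray(weights, dtype=np.float32))
    if s.shape[1] != pair.c_source or t.shape[1] != pair.c_target:
        raise ValueError(
            f"shape mismatch: pair expects C_s={pair.c_source}, C_t={pair.c_target}; "
            f"got {s.shape[1]}, {t.shape[1]}")
    sn = _l2_normalize_maps(nn.resize_bilinear(s, t.shape[2], t.shape[3]))
    tn = _l2_normalize_maps(pair.aligner(t))
    return _weighted_map_distance(sn, tn, w, pair.c_source)


def _weighted_map_distance(sn: Tensor, tn: Tensor, w: Tensor, c_source: int) -> Tensor:
    diff = sn - tn
    d2 = (diff * diff).sum(axis=(2, 3))  # [B, C_s]
    return ((w * d2).sum(axis=1) * (1.0 / c_source)).mean()


def modality_adapter_matrix(c_out: int, c_in: int) -> np.ndarray:
    """Fixed channel-interpolation map used to present target-modality image
    planes to a source encoder trained on a different plane count.  Linear
    interpolation over the plane index preserves spatial structure and is
    deterministic; it is not trained."""
    return nn.interp_matrix(c_out, c_in, dtype=np.float64).astype(np.float32)


@dataclass
class FeatureMatcher:
    """The trainable matching apparatus for a (source, target) encoder pair."""

    pairs: list        # MatchPair per candidate pairing
    weight_nets: list  # WeightNet per candidate pairing
    candidate_pairs: tuple
    adapter: np.ndarray | None = None  # fixed modality adapter (C_src_in x C_img)

    def parameters(self):
        out = []
        for p in self.pairs:
            out.extend(p.parameters())
        for wn in self.weight_nets:
            out.extend(wn.parameters())
        return [p for p in out if p.requires_grad]

    def adapt_images(self, images: np.ndarray) -> np.ndarray:
        if self.adapter is None:
            return images
        return np.einsum("oc,bchw->bohw", self.adapter, images).astype(np.float32)

    def mean_channel_weights(self, source_maps_by_stage: dict) -> dict:
        """Mean learned weight per source channel for every pair, evaluated on
        cached source maps (numpy, [N, C_s, h, w])."""
        out = {}
        for (k, d), wn in zip(self.candidate_pairs, self.weight_nets):
            w = pair_weights(wn, source_maps_by_stage[k])
            out[(k, d)] = w.data.mean(axis=0)
        return out

    def report(self, source_maps_by_stage: dict, history: dict) -> dict:
        """Machine-readable transfer report: per-pair mean weights and the
        per-epoch loss components."""
        weights = self.mean_channel_weights(source_maps_by_stage)
        return {
            "pairs": [
                {"source_stage": int(k), "target_stage": int(d),
                 "mean_weights": [float(v) for v in weights[(k, d)]]}
                for (k, d) in self.candidate_pairs
            ],
            "loss_history": {"cross_entropy": list(map(float, history.get("ce", []))),
                             "matching": list(map(float, history.get("extra", [])))},
        }


def _precompute_source_maps(source: Encoder, images: np.ndarray, batch_size: int = 32) -> list:
    """Frozen-source stage outputs for every image, as numpy arrays."""
    source.eval()
    per_stage = None
    for i in range(0, images.shape[0], batch_size):
        _, fmaps = source.forward(Tensor(images[i : i + batch_size]), want_taps=True)
        arrs = [m.data for m in fmaps.maps]
        if per_stage is None:
            per_stage = [[a] for a in arrs]
        else:
            for lst, a in zip(per_stage, arrs):
                lst.append(a)
    return [np.concatenate(lst, axis=0) for lst in per_stage]


def transfer_train(source: Encoder, target: Encoder, matcher: FeatureMatcher | None,
                   images: np.ndarray, labels: np.ndarray,
                   hyper: TransferHyper) -> tuple:
    """Distill the frozen source encoder into the target encoder.

    Minimizes ``CE(target(x), y) + beta * sum_pairs matching_loss`` jointly
    over the target encoder, the per-pair weight networks and channel
    aligners.  The source encoder must be frozen; its weights are verified
    unchanged.  Returns ``(target, matcher, history)`` where history holds the
    per-epoch cross-entropy and matching components.

    With ``beta == 0`` the matching machinery is bypassed entirely and the
    run is bit-identical to plain cross-entropy training under the same seed.
    """
    if hyper.beta < 0:
        raise ValueError("beta must be >= 0")
    if any(p.requires_grad for p in source.parameters()):
        raise ValueError("source encoder must be frozen before transfer_train")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("target data must contain both classes")
    images = np.asarray(images, dtype=np.float32)

    train_hyper = TrainHyper(epochs=hyper.epochs, lr=hyper.lr, momentum=hyper.momentum,
                             batch_size=hyper.batch_size, cosine_decay=hyper.cosine_decay,
                             seed=hyper.seed)
    src_hash_before = source.weights_hash()

    if hyper.beta == 0:
        history = fit_encoder(target, images, labels, train_hyper)
        assert source.weights_hash() == src_hash_before
        return target, matcher, history

    cand = hyper.candidate_pairs or default_candidate_pairs(len(target.spec.tap_points))
    if matcher is None:
        rng = np.random.default_rng(np.random.SeedSequence([hyper.seed & 0x7FFFFFFF, 0x5EED]))
        sw, tw = source.spec.stage_widths, target.spec.stage_widths
        adapter = None
        if source.spec.in_channels != images.shape[1]:
            adapter = modality_adapter_matrix(source.spec.in_channels, images.shape[1])
        matcher = FeatureMatcher(
            pairs=[MatchPair(k, d, sw[k], tw[d], rng=rng) for (k, d) in cand],
            weight_nets=[WeightNet(sw[k], rng=rng) for (k, _) in cand],
            candidate_pairs=tuple(cand),
            adapter=adapter,
        )

    src_inputs = matcher.adapt_images(images)
    source_maps = _precompute_source_maps(source, src_inputs, batch_size=hyper.batch_size)

    # target tap spatial sizes (dry run on one sample) for source-map pre-resize
    target.eval()
    _, t_fmaps = target.forward(Tensor(images[:1]), want_taps=True)
    t_shapes = [m.shape for m in t_fmaps.maps]

    # Per pair, precompute the L2-normalized spatially-resized source maps and
    # the pooled source vectors: both are constants of the optimization.
    cached = []
    for (k, d), pair, wn in zip(matcher.candidate_pairs, matcher.pairs, matcher.weight_nets):
        s = source_maps[k]
        ht, wt = t_shapes[d][2], t_shapes[d][3]
        ah = nn.interp_matrix(ht, s.shape[2], dtype=np.float32)
        aw = nn.interp_matrix(wt, s.shape[3], dtype=np.float32)
        sr = np.matmul(np.matmul(ah, s), aw.T)
        norm = np.sqrt((sr * sr).sum(axis=(2, 3), keepdims=True) + _EPS)
        sn = (sr / norm).astype(np.float32)
        pooled = s.mean(axis=(2, 3)).astype(np.float32)
        cached.append((pair, wn, d, sn, pooled))

    beta = float(hyper.beta)

    def hook(x: Tensor, idx: np.ndarray, taps) -> Tensor:
        total = None
        for pair, wn, d, sn_all, pooled_all in cached:
            w = wn(Tensor(pooled_all[idx]))
            tn = _l2_normalize_maps(pair.aligner(taps.maps[d]))
            loss = _weighted_map_distance(Tensor(sn_all[idx]), tn, w, pair.c_source)
            total = loss if total is None else total + loss
        return total * beta

    history = fit_encoder(target, images, labels, train_hyper,
                          extra_params=matcher.parameters(), batch_loss_hook=hook)
    assert source.weights_hash() == src_hash_before, "source encoder was mutated during transfer"
    return target, matcher, history
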