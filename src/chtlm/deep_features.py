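"""Per-kernel deep features and nonparametric feature filtering.

Every main-path convolution kernel of the (trained) target encoder acts as a
feature extractor: the spatial mean of its activation map is one deep
feature, giving 3,904 features for ResNet-18 (248 for the tiny test
variant).  Features are then screened with the two-sided Mann–Whitney U test
between MI and rest trials; only features with p below ``alpha`` feed the
classifier.  Filtering must be computed on training-fold rows only — the
selection is part of the fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .encoders import Encoder, count_feature_kernels
from .nn import Tensor

__all__ = [
    "FeatureTable",
    "FilterResult",
    "extract_kernel_features",
    "kernel_feature_ids",
    "mann_whitney_u",
    "filter_features",
]


@dataclass
class FeatureTable:
    """Trials-by-features matrix of per-kernel deep features."""

    X: np.ndarray
    feature_ids: list
    labels: np.ndarray
    subject_ids: list | np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2:
            raise ValueError("X must be [n_trials, n_features]")
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature_ids length must equal n_features")
        if self.labels.shape[0] != self.X.shape[0]:
            raise ValueError("labels length must equal n_trials")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains NaN or Inf")


@dataclass
class FilterResult:
    """Per-feature p-values and the selection mask at level alpha."""

    p_values: np.ndarray
    selected: np.ndarray
    alpha: float
    fallback_used: bool = False


def kernel_feature_ids(enc: Encoder) -> list:
    """(layer, kernel index) identifiers in network forward order: the stem
    convolution, then conv1/conv2 of every basic block."""
    ids = [("stem", i) for i in range(enc.stem_conv.weight.shape[0])]
    for si, blocks in enumerate(enc.stages):
        for bi, blk in enumerate(blocks):
            for ci, conv in enumerate((blk.conv1, blk.conv2)):
                layer = f"stage{si + 1}.block{bi}.conv{ci + 1}"
                ids.extend((layer, i) for i in range(conv.weight.shape[0]))
    return ids


def extract_kernel_features(enc: Encoder, images, labels=None, subject_ids=None,
                            batch_size: int = 32) -> FeatureTable:
    """Spatially averaged activation of every main-path convolution kernel.

    ``images`` is an NCHW array (or a list of TimeFreqImage pixel stacks).
    The encoder is run in eval mode; extraction is deterministic and
    independent of batch composition.
    """
    if hasattr(images, "pixels"):
        images = images.pixels[None]
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4:
        raise ValueError("images must be [n_trials, planes, h, w]")
    if images.shape[1] != enc.spec.in_channels:
        raise ValueError(
            f"channel mismatch: encoder expects {enc.spec.in_channels} planes, got {images.shape[1]}")
    enc.eval()
    rows = []
    for i in range(0, images.shape[0], batch_size):
        _, sink = enc.forward(Tensor(images[i : i + batch_size]), collect_kernels=True)
        feats = [m.data.mean(axis=(2, 3)) for m in sink]
        rows.append(np.concatenate(feats, axis=1))
    X = np.concatenate(rows, axis=0) if rows else np.empty((0, count_feature_kernels(enc.spec)))
    ids = kernel_feature_ids(enc)
    assert X.shape[1] == count_feature_kernels(enc.spec) == len(ids)
    if labels is None:
        labels = np.zeros(X.shape[0], dtype=int)
    return FeatureTable(X=X, feature_ids=ids, labels=labels, subject_ids=subject_ids)


# ------------------------------------------------------------- Mann-Whitney U
_EXACT_N = 12


def _u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of U over all C(n1+n2, n1) rank assignments.

    counts[u] = number of assignments with U statistic u; computed by the
    standard recurrence c(m, n, u) = c(m-1, n, u-n) + c(m, n-1, u).
    """
    umax = n1 * n2
    c = np.zeros((n1 + 1, n2 + 1, umax + 1), dtype=np.int64)
    c[0, :, 0] = 1
    c[:, 0, 0] = 1
    for m in range(1, n1 + 1):
        for n in range(1, n2 + 1):
            c[m, n, :] = c[m, n - 1, :]
            c[m, n, n:] += c[m - 1, n, : umax + 1 - n]
    return c[n1, n2]


def mann_whitney_u(x, y) -> tuple:
    """Two-sided Mann–Whitney U test.

    Returns ``(U, p)`` with U the min-side statistic
    ``min(U_xy, U_yx)`` where ``U_xy = #{x_i > y_j} + 0.5 #{x_i == y_j}``.
    The p-value is exact (full enumeration of the null U distribution) for
    tie-free samples with ``n1 + n2 <= 12``, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    ranks = _sps.rankdata(combined)  # midranks
    r1 = ranks[:n1].sum()
    u_xy = r1 - n1 * (n1 + 1) / 2.0
    u_yx = n1 * n2 - u_xy
    u = min(u_xy, u_yx)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if not has_ties and n1 + n2 <= _EXACT_N:
        counts = _u_counts(n1, n2)
        total = counts.sum()
        p = 2.0 * counts[: int(u) + 1].sum() / total
        return float(u), float(min(1.0, p))
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return float(u), 1.0
    z = (u - mu + 0.5) / math.sqrt(var)  # continuity correction toward the mean
    p = 2.0 * _sps.norm.cdf(z)
    return float(u), float(min(1.0, max(0.0, p)))


def filter_features(table: FeatureTable, alpha: float = 0.05,
                    fallback_k: int = 32) -> FilterResult:
    """Screen features by two-sided Mann–Whitney p between MI and rest rows.

    Must be given training rows only.  Features with ``p < alpha`` are
    selected; if none pass, the ``fallback_k`` smallest-p features are kept so
    the downstream classifier always has inputs.
    """
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ValueError("filter_features requires both classes in the labels")
    a = table.X[table.labels == classes[1]]  # MI
    b = table.X[table.labels == classes[0]]  # rest
    p = np.empty(table.X.shape[1])
    for j in range(table.X.shape[1]):
        _, p[j] = mann_whitney_u(a[:, j], b[:, j])
    # p < alpha, except alpha >= 1 which by the threshold contract keeps all
    # features (a p-value of exactly 1.0 is attainable under the two-sided cap)
    selected = (p < alpha) if alpha < 1.0 else np.ones_like(p, dtype=bool)
    fallback = False
    if not selected.any():
        fallback = True
        k = min(fallback_k, len(p))
        selected = np.zeros_like(selected)
        selected[np.argsort(p)[:k]] = True
    return FilterResult(p_values=p, selected=selected, alpha=alpha, fallback_used=fallback)
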