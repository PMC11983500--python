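"""Leave-one-subject-out evaluation of the full transfer pipeline.

Each fold holds out one subject: the target encoder is transfer-trained,
features are extracted, the Mann–Whitney screen and the SBELM classifier are
fitted on the remaining subjects only, and the held-out subject's trials are
scored.  MI is the positive class.  Metrics: accuracy, AUC (rank statistic,
ties credited ½), recall, precision, F1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .containers import TrialSet
from .deep_features import extract_kernel_features, filter_features
from .encoders import EncoderSpec, build_encoder
from .feature_matching import TransferHyper, transfer_train
from .preprocess import trials_to_images
from .sbelm import SBELM

__all__ = ["PipelineConfig", "FoldResult", "compute_metrics", "rank_auc", "loo_cv"]


def rank_auc(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """AUC as the normalized Mann–Whitney rank statistic of the scores; tied
    scores count ½.  Returns None when only one class is present."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[y_true == 1]
    neg = scores[y_true != 1]
    if len(pos) == 0 or len(neg) == 0:
        return None
    ranks = _sps.rankdata(scores)
    r_pos = ranks[y_true == 1].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(neg)))


def compute_metrics(y_true, scores, y_pred) -> dict:
    """Binary classification metrics with MI (1) as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("y_true, scores and y_pred must have equal length")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    accuracy = float(np.mean(y_pred == y_true)) if len(y_true) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return {
        "accuracy": accuracy,
        "auc": rank_auc(y_true, scores),
        "recall": float(recall),
        "precision": float(precision),
        "f1": float(f1),
    }


@dataclass
class FoldResult:
    """Held-out-subject predictions and metrics for one CV fold."""

    subject_id: str
    y_true: np.ndarray
    scores: np.ndarray
    y_pred: np.ndarray
    metrics: dict
    n_selected_features: int = 0


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (encoders, imaging, transfer, classifier)."""

    target_variant: str = "tiny18"
    source_variant: str = "tiny34"
    image_size: int = 64
    n_scales: int = 16
    wavelet: str = "cmor1.5-1.0"
    fnirs_band: tuple = (0.01, 0.2)
    eeg_band: tuple = (4.0, 40.0)
    stft_window_s: float = 0.5
    stft_overlap: float = 0.5
    beta: float = 0.5
    transfer_epochs: int = 8
    transfer_lr: float = 0.01
    source_epochs: int = 15
    source_lr: float = 0.01
    batch_size: int = 16
    alpha: float = 0.05
    sbelm_L: int = 200
    seed: int = 0

    def imaging_kwargs(self) -> dict:
        return dict(out_size=self.image_size, n_scales=self.n_scales, wavelet=self.wavelet,
                    stft_window_s=self.stft_window_s, stft_overlap=self.stft_overlap,
                    eeg_band=self.eeg_band, fnirs_band=self.fnirs_band)


def _subject_images(subjects: dict, cfg: PipelineConfig) -> dict:
    return {sid: trials_to_images(ts, **cfg.imaging_kwargs()) for sid, ts in subjects.items()}


def loo_cv(subjects: dict, source_encoder, cfg: PipelineConfig,
           subject_images: dict | None = None) -> tuple:
    """Leave-one-subject-out cross-validation of the transfer pipeline.

    Parameters
    ----------
    subjects : mapping subject_id -> fnirs-hemo TrialSet.
    source_encoder : trained, frozen source encoder (or None for beta = 0).
    cfg : pipeline configuration; per-fold seeds are ``cfg.seed + fold``.
    subject_images : optional precomputed {subject_id: NCHW image array}
        cache (images are deterministic functions of the trials).

    Returns ``(fold_results, mean_metrics)``; the mean row is the unweighted
    arithmetic mean over subjects.  Folds whose AUC is undefined (single-class
    test data) are excluded from the AUC mean with a warning.
    """
    sids = list(subjects.keys())
    if len(sids) < 2:
        raise ValueError("loo_cv requires at least 2 subjects")
    if subject_images is None:
        subject_images = _subject_images(subjects, cfg)
    planes = next(iter(subject_images.values())).shape[1]
    folds = []
    for fold, held_out in enumerate(sids):
        fold_seed = cfg.seed + fold
        train_ids = [s for s in sids if s != held_out]
        X_img = np.concatenate([subject_images[s] for s in train_ids], axis=0)
        y = np.concatenate([subjects[s].labels for s in train_ids])
        target = build_encoder(EncoderSpec(cfg.target_variant, in_channels=planes,
                                           n_classes=2, seed=fold_seed))
        hyper = TransferHyper(beta=cfg.beta if source_encoder is not None else 0.0,
                              epochs=cfg.transfer_epochs, lr=cfg.transfer_lr,
                              batch_size=cfg.batch_size, seed=fold_seed)
        target, matcher, history = transfer_train(source_encoder, target, None, X_img, y, hyper) \
            if source_encoder is not None else _plain_train(target, X_img, y, hyper)
        # feature extraction + screening on training rows only
        table = extract_kernel_features(target, X_img, labels=y)
        filt = filter_features(table, alpha=cfg.alpha)
        clf = SBELM(L=cfg.sbelm_L, seed=fold_seed)
        clf.fit(table.X[:, filt.selected], y)
        X_test = extract_kernel_features(target, subject_images[held_out]).X[:, filt.selected]
        scores, y_pred = clf.predict(X_test)
        y_true = subjects[held_out].labels
        folds.append(FoldResult(subject_id=held_out, y_true=y_true, scores=scores,
                                y_pred=y_pred, metrics=compute_metrics(y_true, scores, y_pred),
                                n_selected_features=int(filt.selected.sum())))
    mean = mean_metrics([f.metrics for f in folds])
    return folds, mean


def _plain_train(target, X_img, y, hyper):
    from .encoders import TrainHyper, fit_encoder

    th = TrainHyper(epochs=hyper.epochs, lr=hyper.lr, momentum=hyper.momentum,
                    batch_size=hyper.batch_size, cosine_decay=hyper.cosine_decay,
                    seed=hyper.seed)
    history = fit_encoder(target, X_img, y, th)
    return target, None, history


def mean_metrics(rows: list) -> dict:
    """Unweighted mean of per-subject metrics; undefined AUCs are skipped."""
    out = {}
    for key in ("accuracy", "auc", "recall", "precision", "f1"):
        vals = [r[key] for r in rows if r[key] is not None]
        if key == "auc" and len(vals) < len(rows):
            warnings.warn("AUC undefined for some folds (single-class test data); "
                          "excluded from the mean")
        out[key] = float(np.mean(vals)) if vals else None
    return out
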