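"""Readers and writers: TrialSet containers, SNIRF and columnar CSV/TSV
recordings, encoder checkpoints, and classifier persistence.

TrialSets are persisted as a ``.npy`` array with a ``.json`` sidecar carrying
labels, sampling rate, modality and channel names; trials can also be
exported to per-trial CSV for eyeballing.  The SNIRF reader covers the
subset of the format the pipeline needs: continuous-wave amplitude
(dataType 1) grouped into source-detector channels, and processed
HbO/HbR series (dataTypeLabel).  The EEG GDF adapter is feature-gated on
``mne`` being importable.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .containers import HemoRecording, OpticalRecording, TrialSet
from .encoders import Encoder, EncoderSpec, build_encoder
from .sbelm import SBELM

__all__ = [
    "save_trialset", "load_trialset", "export_trials_csv",
    "read_snirf", "read_csv_recording", "read_events_csv", "read_gdf_trials",
    "save_encoder", "load_encoder", "save_sbelm", "load_sbelm",
]


# ------------------------------------------------------------------ TrialSet
def save_trialset(ts: TrialSet, path) -> Path:
    """Write ``<path>.npy`` (data) + ``<path>.json`` (metadata sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), ts.data)
    meta = {
        "labels": [int(v) for v in ts.labels],
        "subject_id": ts.subject_id,
        "modality": ts.modality,
        "fs": ts.fs,
        "channel_names": ts.channel_names,
        "class_names": list(ts.class_names) if ts.class_names else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".npy")


def load_trialset(path) -> TrialSet:
    path = Path(path)
    data = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return TrialSet(data=data, labels=np.asarray(meta["labels"]),
                    subject_id=meta["subject_id"], modality=meta["modality"],
                    fs=meta["fs"], channel_names=meta["channel_names"],
                    class_names=tuple(meta["class_names"]) if meta.get("class_names") else None)


def export_trials_csv(ts: TrialSet, out_dir) -> list:
    """One CSV per trial (columns = channels, rows = samples)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = ts.channel_names or [f"ch{i}" for i in range(ts.n_channels)]
    paths = []
    for k in range(ts.n_trials):
        p = out_dir / f"{ts.subject_id}_trial{k:03d}_label{int(ts.labels[k])}.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(names)
            w.writerows(ts.data[k].T)
        paths.append(p)
    return paths


# --------------------------------------------------------------------- SNIRF
def read_snirf(path):
    """Read a SNIRF file into an OpticalRecording (CW amplitude) or a
    HemoRecording (processed HbO/HbR), depending on its measurement list."""
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f["nirs"] if "nirs" in f else f["nirs1"]
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])  # [time, measurement]
        t = np.asarray(data["time"]).ravel()
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-3):
                raise ValueError("SNIRF time axis is not uniformly sampled")
            fs = 1.0 / float(dt[0])
        else:
            fs = 1.0
        wavelengths = None
        if "probe" in nirs and "wavelengths" in nirs["probe"]:
            wavelengths = tuple(np.asarray(nirs["probe"]["wavelengths"]).ravel()[:2])
        ml = []
        i = 1
        while f"measurementList{i}" in data:
            g = data[f"measurementList{i}"]
            entry = {
                "source": int(np.asarray(g["sourceIndex"])),
                "detector": int(np.asarray(g["detectorIndex"])),
                "dtype": int(np.asarray(g["dataType"])) if "dataType" in g else 1,
                "wl": int(np.asarray(g["wavelengthIndex"])) if "wavelengthIndex" in g else 0,
                "label": (np.asarray(g["dataTypeLabel"]).item() if "dataTypeLabel" in g else b""),
            }
            if isinstance(entry["label"], bytes):
                entry["label"] = entry["label"].decode()
            ml.append(entry)
            i += 1
    if not ml:
        raise ValueError("SNIRF file has no measurementList entries")
    labels = {m["label"] for m in ml}
    pairs = sorted({(m["source"], m["detector"]) for m in ml})
    names = [f"S{s}D{d}" for s, d in pairs]
    if {"HbO", "HbR"} <= labels:
        def col(pair, lab):
            for k, m in enumerate(ml):
                if (m["source"], m["detector"]) == pair and m["label"] == lab:
                    return k
            raise ValueError(f"SNIRF channel {pair} missing {lab} series")
        hbo = np.stack([series[:, col(p, "HbO")] for p in pairs]).astype(np.float64)
        hbr = np.stack([series[:, col(p, "HbR")] for p in pairs]).astype(np.float64)
        return HemoRecording(hbo=hbo, hbr=hbr, fs=fs, channel_names=names)
    # continuous-wave amplitude: two wavelengths per source-detector pair
    def col_wl(pair, wl):
        for k, m in enumerate(ml):
            if (m["source"], m["detector"]) == pair and m["wl"] == wl:
                return k
        raise ValueError(f"SNIRF channel {pair} missing wavelength index {wl}")
    inten = np.stack([
        np.stack([series[:, col_wl(p, 1)], series[:, col_wl(p, 2)]]) for p in pairs
    ]).astype(np.float64)
    kw = {}
    if wavelengths is not None and len(wavelengths) == 2:
        kw["wavelengths"] = tuple(float(w) for w in wavelengths)
    return OpticalRecording(intensity=inten, fs=fs, channel_names=names, **kw)


# ------------------------------------------------------------------- CSV/TSV
def read_csv_recording(path, fs: float | None = None, kind: str = "hemo"):
    """Columnar recording: one column per channel, header row of channel
    names; an optional ``time`` column supplies the sampling rate.

    ``kind='hemo'`` expects ``*_HbO`` / ``*_HbR`` column pairs and returns a
    HemoRecording; ``kind='raw'`` expects ``*_w<nm>`` columns and returns an
    OpticalRecording.
    """
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path) as fh:
        rows = list(csv.reader(fh, delimiter=delim))
    header, body = rows[0], rows[1:]
    arr = np.asarray(body, dtype=np.float64)
    cols = {name: arr[:, k] for k, name in enumerate(header)}
    if "time" in cols:
        t = cols.pop("time")
        dt = np.diff(t)
        fs = 1.0 / float(np.median(dt))
    if fs is None:
        raise ValueError("sampling rate: provide fs or a 'time' column")
    if kind == "hemo":
        base = [n[: -len("_HbO")] for n in cols if n.endswith("_HbO")]
        missing = [b for b in base if f"{b}_HbR" not in cols]
        if not base or missing:
            raise ValueError(f"hemo CSV needs *_HbO/*_HbR column pairs (missing HbR for {missing})")
        hbo = np.stack([cols[f"{b}_HbO"] for b in base])
        hbr = np.stack([cols[f"{b}_HbR"] for b in base])
        return HemoRecording(hbo=hbo, hbr=hbr, fs=fs, channel_names=base)
    base, wl = [], {}
    for n in cols:
        stem, _, w = n.rpartition("_w")
        if stem and w.isdigit():
            wl.setdefault(stem, {})[int(w)] = cols[n]
            if stem not in base:
                base.append(stem)
    if not base:
        raise ValueError("raw CSV needs *_w<nm> columns (e.g. CH01_w730, CH01_w850)")
    inten = np.stack([np.stack([v for _, v in sorted(wl[b].items())]) for b in base])
    return OpticalRecording(intensity=inten, fs=fs, channel_names=base)


def read_events_csv(path) -> list:
    """Event table with columns onset_s,label -> [(onset_s, label), ...]."""
    path = Path(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path) as fh:
        rows = list(csv.DictReader(fh, delimiter=delim))
    return [(float(r["onset_s"]), r["label"]) for r in rows]


def read_gdf_trials(path, tmin: float = 0.0, tmax: float = 4.0) -> TrialSet:
    """Optional adapter for GDF-format EEG (BCI Competition IV 2a style).

    Requires ``mne``; raises ImportError with guidance when it is absent so
    the rest of the package works without it.
    """
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading GDF files requires the optional 'mne' dependency "
                          "(pip install chtlm[gdf])") from e
    raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True)
    epochs = mne.Epochs(raw, events, event_id=event_id, tmin=tmin, tmax=tmax,
                        baseline=None, picks=picks, preload=True, verbose="error")
    labels = epochs.events[:, 2]
    _, uniq = np.unique(labels, return_inverse=True)
    return TrialSet(data=epochs.get_data(), labels=uniq, subject_id=Path(path).stem,
                    modality="eeg", fs=float(raw.info["sfreq"]),
                    channel_names=[raw.ch_names[p] for p in picks])


# --------------------------------------------------------------- checkpoints
def save_encoder(enc: Encoder, path) -> Path:
    """Portable checkpoint: npz of parameters + batch-norm statistics, with a
    JSON manifest describing the architecture."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p::{name}": p.data for name, p in enc.named_parameters()}
    from .nn.layers import BatchNorm2d

    for i, m in enumerate(enc.modules()):
        if isinstance(m, BatchNorm2d):
            arrays[f"bn{i}::mean"] = m.running_mean
            arrays[f"bn{i}::var"] = m.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    spec = enc.spec
    manifest = {
        "variant": spec.variant, "in_channels": spec.in_channels,
        "n_classes": spec.n_classes, "seed": spec.seed, "frozen": bool(enc.frozen),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path.with_suffix(".npz")


def load_encoder(path) -> Encoder:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    enc = build_encoder(EncoderSpec(manifest["variant"], in_channels=manifest["in_channels"],
                                    n_classes=manifest["n_classes"], seed=manifest["seed"]))
    with np.load(path.with_suffix(".npz")) as z:
        params = dict(enc.named_parameters())
        from .nn.layers import BatchNorm2d

        bns = {f"bn{i}": m for i, m in enumerate(enc.modules()) if isinstance(m, BatchNorm2d)}
        for key in z.files:
            tag, _, name = key.partition("::")
            if tag == "p":
                params[name].data = z[key].copy()
            elif tag in bns:
                if name == "mean":
                    bns[tag].running_mean = z[key].copy()
                else:
                    bns[tag].running_var = z[key].copy()
    enc.eval()
    if manifest.get("frozen"):
        enc.freeze()
        enc.frozen = True
    return enc


def save_sbelm(clf: SBELM, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if clf.beta_out is None:
        raise ValueError("cannot persist an unfitted SBELM")
    np.savez(path.with_suffix(".npz"), W=clf.W, b=clf.b, beta_out=clf.beta_out,
             mean=clf._mean, sd=clf._sd)
    manifest = {"L": clf.L, "activation": clf.activation, "seed": clf.seed,
                "lambda": clf.lambda_, "plain_elm": clf.plain_elm}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
    return path.with_suffix(".npz")


def load_sbelm(path) -> SBELM:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    clf = SBELM(L=manifest["L"], activation=manifest["activation"],
                seed=manifest["seed"], plain_elm=manifest["plain_elm"])
    with np.load(path.with_suffix(".npz")) as z:
        clf.W, clf.b = z["W"].copy(), z["b"].copy()
        clf.beta_out = z["beta_out"].copy()
        clf._mean, clf._sd = z["mean"].copy(), z["sd"].copy()
    clf.lambda_ = manifest["lambda"]
    return clf
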