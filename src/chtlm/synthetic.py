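"""Synthetic EEG/fNIRS trial generators with known class structure.

The fNIRS generator emulates the block motor-imagery paradigm used for the
target domain: MI trials carry a canonical-HRF-convolved boxcar response on a
"contralateral" half of the channels (scaled by a per-subject lognormal gain
and shifted by a per-subject latency), HbR is anticorrelated with HbO₂
(-0.3x), and all trials ride on 1/f physiological noise plus a ~0.1 Hz
Mayer-wave oscillation sitting just inside the analysis passband.  Rest
trials contain noise only.  The hemodynamic trials can be mapped back to raw
dual-wavelength optical intensities, making the Beer–Lambert conversion
exactly round-trippable.

The EEG generator emulates mu-band (8–13 Hz) power modulation with a
class-specific spatial pattern over 1/f background noise — the
event-related-(de)synchronization structure a band-power classifier exploits.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import ConfigError, ExtinctionMatrix, TrialSet, default_extinction

__all__ = [
    "SynthConfig",
    "double_gamma_hrf",
    "hrf_response",
    "generate_fnirs_subject",
    "generate_eeg_subject",
    "hemo_to_raw_intensity",
    "raw_trial_to_optical",
    "oneoverf_noise",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition parameters of the synthetic generators.

    Defaults mirror the target paradigm: 10 MI + 10 rest trials per subject,
    16 fNIRS channels at 11 Hz, 15 s imagery per trial; EEG at 250 Hz over
    22 channels with 4 s trials.
    """

    n_subjects: int = 8
    trials_per_class: int = 10
    fs_fnirs: float = 11.0
    fs_eeg: float = 250.0
    n_channels_fnirs: int = 16
    n_channels_eeg: int = 22
    task_s: float = 15.0
    rest_s: float = 20.0
    eeg_trial_s: float = 4.0
    effect_amp: float = 1.0
    noise_sd: float = 1.0
    subject_gain_sd: float = 0.4
    subject_latency_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        for f in ("n_subjects", "trials_per_class", "n_channels_fnirs", "n_channels_eeg"):
            if getattr(self, f) < 1:
                raise ConfigError(f"{f}: must be >= 1")
        for f in ("fs_fnirs", "fs_eeg", "task_s", "rest_s", "eeg_trial_s"):
            if getattr(self, f) <= 0:
                raise ConfigError(f"{f}: must be > 0")
        if self.effect_amp < 0:
            raise ConfigError("effect_amp: must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd: must be > 0")
        if self.subject_gain_sd < 0:
            raise ConfigError("subject_gain_sd: must be >= 0")
        if self.subject_latency_sd < 0:
            raise ConfigError("subject_latency_sd: must be >= 0")


def _subject_rng(cfg_seed: int, subject_id: str, stream: int = 0) -> np.random.Generator:
    """Deterministic per-subject generator: identical (config, seed, subject)
    always yields bit-identical data."""
    sid = zlib.crc32(str(subject_id).encode())
    return np.random.default_rng(np.random.SeedSequence([cfg_seed & 0x7FFFFFFF, sid, stream]))


# ------------------------------------------------------------------ HRF model
def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s,
    undershoot ratio 1/6), normalized to unit peak."""
    t = np.asarray(t, dtype=np.float64)
    h = stats.gamma.pdf(t, peak_s) - ratio * stats.gamma.pdf(t, undershoot_s)
    m = h.max()
    return h / m if m > 0 else h


def hrf_response(n_samples: int, fs: float, onset_s: float, duration_s: float) -> np.ndarray:
    """Boxcar (onset, duration) convolved with the canonical HRF, sampled at
    fs, truncated to ``n_samples`` and normalized to unit peak — so the
    generator's ``effect_amp`` is directly the peak response amplitude in the
    same units as ``noise_sd`` (i.e. the single-trial contrast-to-noise
    ratio when ``noise_sd`` is 1)."""
    t = np.arange(n_samples) / fs
    box = ((t >= onset_s) & (t < onset_s + duration_s)).astype(np.float64)
    hrf_t = np.arange(0, 32.0, 1.0 / fs)
    resp = np.convolve(box, double_gamma_hrf(hrf_t))[:n_samples]
    m = resp.max()
    return resp / m if m > 0 else resp


# ---------------------------------------------------------------------- noise
def oneoverf_noise(rng: np.random.Generator, shape: tuple, fs: float, sd: float,
                   exponent: float = 1.0) -> np.ndarray:
    """1/f^a noise via spectral shaping of white noise; last axis is time.
    Zero mean, standard deviation ``sd`` per series."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * gain, n=n, axis=-1)
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return sd * x / s


# --------------------------------------------------------------- fNIRS trials
def generate_fnirs_subject(cfg: SynthConfig, subject_id: str) -> TrialSet:
    """Synthesize one subject's hemodynamic MI/rest trials (modality fnirs-hemo).

    Channel stacking is HbO₂ planes then HbR planes; the first half of the
    optode channels is the "contralateral" active set.
    """
    rng = _subject_rng(cfg.seed, subject_id)
    n_ch = cfg.n_channels_fnirs
    n = int(round(cfg.task_s * cfg.fs_fnirs))
    n_trials = 2 * cfg.trials_per_class
    gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_sd))) if cfg.subject_gain_sd > 0 else 1.0
    latency = float(rng.normal(0.0, cfg.subject_latency_sd)) if cfg.subject_latency_sd > 0 else 0.0
    labels = np.array([1] * cfg.trials_per_class + [0] * cfg.trials_per_class)
    rng.shuffle(labels)
    active = np.zeros(n_ch)
    active[: n_ch // 2] = 1.0  # contralateral half of the montage
    resp = hrf_response(n, cfg.fs_fnirs, max(0.0, latency), cfg.task_s)
    data = np.empty((n_trials, 2 * n_ch, n))
    for k in range(n_trials):
        hbo = oneoverf_noise(rng, (n_ch, n), cfg.fs_fnirs, cfg.noise_sd)
        hbr = oneoverf_noise(rng, (n_ch, n), cfg.fs_fnirs, cfg.noise_sd)
        # Mayer wave: shared frequency per trial, random phase per channel
        fm = rng.uniform(0.095, 0.105)
        t = np.arange(n) / cfg.fs_fnirs
        ph = rng.uniform(0, 2 * np.pi, size=(2, n_ch, 1))
        mayer = 0.5 * cfg.noise_sd * np.sin(2 * np.pi * fm * t + ph)
        hbo = hbo + mayer[0]
        hbr = hbr + mayer[1]
        if labels[k] == 1:
            task = cfg.effect_amp * gain * np.outer(active, resp)
            hbo = hbo + task
            hbr = hbr - 0.3 * task
        data[k, :n_ch] = hbo
        data[k, n_ch:] = hbr
    names = [f"CH{i + 1:02d}_HbO" for i in range(n_ch)] + [f"CH{i + 1:02d}_HbR" for i in range(n_ch)]
    return TrialSet(data=data, labels=labels, subject_id=str(subject_id),
                    modality="fnirs-hemo", fs=cfg.fs_fnirs, channel_names=names)


# ----------------------------------------------------------------- EEG trials
def generate_eeg_subject(cfg: SynthConfig, subject_id: str,
                         classes=("left", "right")) -> TrialSet:
    """Synthesize one subject's EEG MI trials (modality eeg).

    Each class boosts mu-band oscillatory amplitude on its own channel group
    (a crude spatial pattern of event-related synchronization) over a 1/f
    background; trial length ``eeg_trial_s`` seconds.
    """
    classes = tuple(classes)
    if not classes:
        raise ConfigError("classes: must be nonempty")
    known = {"left", "right", "foot", "tongue"}
    unknown = [c for c in classes if c not in known]
    if unknown:
        raise ValueError(f"unknown class label(s): {unknown}")
    rng = _subject_rng(cfg.seed, subject_id, stream=1)
    n_ch = cfg.n_channels_eeg
    n = int(round(cfg.eeg_trial_s * cfg.fs_eeg))
    n_trials = cfg.trials_per_class * len(classes)
    labels = np.repeat(np.arange(len(classes)), cfg.trials_per_class)
    rng.shuffle(labels)
    # class-specific spatial pattern: contiguous channel group per class
    groups = np.array_split(np.arange(n_ch), len(classes))
    gain = float(np.exp(rng.normal(0.0, cfg.subject_gain_sd))) if cfg.subject_gain_sd > 0 else 1.0
    t = np.arange(n) / cfg.fs_eeg
    data = np.empty((n_trials, n_ch, n))
    base_mu = 0.5 * cfg.noise_sd
    for k in range(n_trials):
        x = oneoverf_noise(rng, (n_ch, n), cfg.fs_eeg, cfg.noise_sd)
        f_mu = rng.uniform(8.0, 13.0)
        ph = rng.uniform(0, 2 * np.pi, size=(n_ch, 1))
        amp = np.full(n_ch, base_mu)
        amp[groups[labels[k]]] *= 1.0 + cfg.effect_amp * gain
        x = x + amp[:, None] * np.sin(2 * np.pi * f_mu * t + ph)
        data[k] = x
    names = [f"EEG{i + 1:02d}" for i in range(n_ch)]
    return TrialSet(data=data, labels=labels, subject_id=str(subject_id), modality="eeg",
                    fs=cfg.fs_eeg, channel_names=names, class_names=classes)


# ------------------------------------------------- inverse Beer-Lambert (raw)
def hemo_to_raw_intensity(trials: TrialSet, eps: ExtinctionMatrix | None = None,
                          dpf=(6.0, 6.0), d_mm: float = 30.0,
                          i0: float = 1.0) -> TrialSet:
    """Map hemodynamic trials back to raw dual-wavelength intensities.

    Inverse of the modified Beer–Lambert conversion: ΔA_λ = (d/10)·DPF_λ·(ε ΔC)_λ
    and I_λ(t) = I₀·10^(−ΔA_λ(t)).  Output channels interleave wavelengths per
    optode channel (CHxx_w730, CHxx_w850, ...); applying the forward conversion
    with the same constants recovers the input to ~1e-8.
    """
    if trials.modality != "fnirs-hemo":
        raise ValueError("hemo_to_raw_intensity requires a fnirs-hemo TrialSet")
    eps = eps or default_extinction()
    dpf = np.asarray(dpf, dtype=np.float64)
    if d_mm <= 0:
        raise ConfigError("d_mm: must be > 0")
    n_ch = trials.n_channels // 2
    hbo = trials.data[:, :n_ch, :]
    hbr = trials.data[:, n_ch:, :]
    conc = np.stack([hbo, hbr], axis=2)  # (trials, ch, 2 chromophores, T)
    delta_a = np.einsum("wc,knct->knwt", eps.eps, conc) * ((d_mm / 10.0) * dpf)[None, None, :, None]
    inten = i0 * 10.0 ** (-delta_a)  # (trials, ch, 2 wavelengths, T)
    flat = inten.reshape(trials.n_trials, 2 * n_ch, trials.n_samples)
    base = [c[: -len("_HbO")] for c in trials.channel_names[:n_ch]] if trials.channel_names else [
        f"CH{i + 1:02d}" for i in range(n_ch)]
    names = [f"{b}_w{w}" for b in base for w in (730, 850)]
    return TrialSet(data=flat, labels=trials.labels.copy(), subject_id=trials.subject_id,
                    modality="fnirs-raw", fs=trials.fs, channel_names=names,
                    class_names=trials.class_names)


def raw_trial_to_optical(trials: TrialSet, trial_index: int, d_mm: float = 30.0,
                         dpf=(6.0, 6.0)):
    """View one raw-intensity trial as an OpticalRecording (for beer_lambert)."""
    from .containers import OpticalRecording

    if trials.modality != "fnirs-raw":
        raise ValueError("expected a fnirs-raw TrialSet")
    n_ch = trials.n_channels // 2
    inten = trials.data[trial_index].reshape(n_ch, 2, trials.n_samples)
    base = [c[: c.rfind("_w")] for c in trials.channel_names[::2]] if trials.channel_names else None
    return OpticalRecording(intensity=inten, fs=trials.fs, d_mm=d_mm, dpf=tuple(dpf),
                            channel_names=base)
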