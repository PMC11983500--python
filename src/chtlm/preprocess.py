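"""Preprocessing of optical and electrophysiological recordings.

Steps implemented: modified Beer–Lambert conversion of raw dual-wavelength
intensities to ΔHbO₂/ΔHbR, channel selection, zero-phase 0.01–0.2 Hz
band-pass filtering, event-based trial segmentation, continuous-wavelet
scalogram images for fNIRS trials and STFT spectrogram images for EEG trials.
"""

from __future__ import annotations

import re

import numpy as np
from scipy import signal
from scipy.fft import fft, ifft, next_fast_len

from .containers import (
    ConfigError,
    ExtinctionMatrix,
    HemoRecording,
    OpticalRecording,
    TimeFreqImage,
    TrialSet,
    default_extinction,
)
from .nn import interp_matrix

__all__ = [
    "beer_lambert",
    "beer_lambert_delta",
    "select_channels",
    "bandpass",
    "segment_trials",
    "paradigm_events",
    "cwt_image",
    "stft_image",
    "trials_to_images",
]


# --------------------------------------------------------------- Beer-Lambert
def beer_lambert_delta(delta_a: np.ndarray, eps: ExtinctionMatrix, d_mm: float, dpf) -> np.ndarray:
    """Invert the modified Beer–Lambert law on optical-density changes.

    ``delta_a`` has shape [..., 2 wavelengths, n_samples]; returns
    concentration changes [..., 2 chromophores (HbO₂, HbR), n_samples],
    using ΔA_λ = (d/10 cm) · DPF_λ · (ε ΔC)_λ.
    """
    dpf = np.asarray(dpf, dtype=np.float64)
    path = (d_mm / 10.0) * dpf  # effective pathlength per wavelength, cm
    y = delta_a / path[:, None]
    return np.einsum("cw,...wt->...ct", eps.inverse, y)


def beer_lambert(opt: OpticalRecording, eps: ExtinctionMatrix | None = None,
                 baseline_window=None, i0=None) -> HemoRecording:
    """Convert raw intensities to ΔHbO₂/ΔHbR via the modified Beer–Lambert law.

    The baseline intensity I₀ is the mean over ``baseline_window`` (a sample
    slice/range), by default the initial 10 s rest period of the recording;
    a known baseline can be supplied directly via ``i0`` (scalar or per
    channel/wavelength), in which case the conversion is the exact inverse of
    :func:`chtlm.synthetic.hemo_to_raw_intensity`.
    """
    eps = eps or default_extinction()
    if i0 is not None:
        a = np.asarray(i0, dtype=np.float64)
        if a.ndim == 2:
            a = a[:, :, None]
        i0 = np.broadcast_to(a, (opt.n_channels, 2, 1)).copy()
    else:
        if baseline_window is None:
            baseline_window = slice(0, max(1, int(round(10.0 * opt.fs))))
        elif not isinstance(baseline_window, slice):
            lo, hi = baseline_window
            baseline_window = slice(int(lo), int(hi))
        idx = range(*baseline_window.indices(opt.n_samples))
        if len(idx) == 0:
            raise ValueError("baseline_window is empty or outside the recording")
        i0 = opt.intensity[:, :, baseline_window].mean(axis=2, keepdims=True)
    delta_a = np.log10(i0 / opt.intensity)  # optical density change
    conc = beer_lambert_delta(delta_a, eps, opt.d_mm, opt.dpf)
    return HemoRecording(hbo=conc[:, 0, :], hbr=conc[:, 1, :], fs=opt.fs,
                         channel_names=list(opt.channel_names))


# ----------------------------------------------------------- channel handling
def select_channels(hemo: HemoRecording, keep) -> HemoRecording:
    """Restrict (and reorder) channels to the given names."""
    keep = list(keep)
    missing = [k for k in keep if k not in hemo.channel_names]
    if missing:
        raise ValueError(f"unknown channel name(s): {missing}")
    order = [hemo.channel_names.index(k) for k in keep]
    return HemoRecording(hbo=hemo.hbo[order], hbr=hemo.hbr[order], fs=hemo.fs,
                         channel_names=keep)


# ------------------------------------------------------------------ filtering
def _bandpass_sos(low: float, high: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2 = {nyq}")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(hemo: HemoRecording, low: float = 0.01, high: float = 0.2) -> HemoRecording:
    """Zero-phase 4th-order Butterworth band-pass, applied per channel and
    chromophore (forward-backward, so HRF latency is not distorted)."""
    sos = _bandpass_sos(low, high, hemo.fs)
    hbo = signal.sosfiltfilt(sos, hemo.hbo, axis=-1)
    hbr = signal.sosfiltfilt(sos, hemo.hbr, axis=-1)
    return HemoRecording(hbo=hbo, hbr=hbr, fs=hemo.fs, channel_names=list(hemo.channel_names))


def measure_bandpass_gain(freq_hz: float, fs: float = 11.0, duration_s: float = 200.0,
                          low: float = 0.01, high: float = 0.2) -> float:
    """Steady-state amplitude gain of :func:`bandpass` at one frequency.

    A unit sinusoid is filtered and its amplitude re-estimated by a
    least-squares sin/cos fit over the central half of the record, which
    excludes the forward-backward filter's edge transients.
    """
    t = np.arange(int(duration_s * fs)) / fs
    x = np.sin(2 * np.pi * freq_hz * t)
    rec = HemoRecording(hbo=x[None, :], hbr=x[None, :], fs=fs)
    y = bandpass(rec, low=low, high=high).hbo[0]
    lo, hi = int(len(t) * 0.25), int(len(t) * 0.75)
    a = np.column_stack([np.sin(2 * np.pi * freq_hz * t[lo:hi]),
                         np.cos(2 * np.pi * freq_hz * t[lo:hi])])
    c, *_ = np.linalg.lstsq(a, y[lo:hi], rcond=None)
    return float(np.hypot(*c))


# --------------------------------------------------------------- segmentation
_MI_LABELS = {1, "1", "mi", "MI", "task"}
_REST_LABELS = {0, "0", "rest", "REST"}


def _label_to_int(label) -> int:
    if label in _MI_LABELS:
        return 1
    if label in _REST_LABELS:
        return 0
    raise ValueError(f"unknown event label {label!r} (expected MI/rest)")


def segment_trials(hemo: HemoRecording, events, task_window_s: float = 10.0,
                   rest_window_s: float = 10.0, subject_id: str = "S?") -> TrialSet:
    """Cut one trial per (onset_s, label) event.

    MI events take ``[onset, onset + task_window_s)``; rest events take
    ``[onset, onset + rest_window_s)``.  HbO₂ and HbR planes are stacked along
    the channel axis (HbO₂ first).
    """
    n_task = int(np.floor(task_window_s * hemo.fs))
    n_rest = int(np.floor(rest_window_s * hemo.fs))
    if n_task != n_rest:
        raise ConfigError(
            "task_window_s/rest_window_s: windows must contain the same number "
            f"of samples (got {n_task} vs {n_rest}); trials must be equal length")
    names = [f"{c}_HbO" for c in hemo.channel_names] + [f"{c}_HbR" for c in hemo.channel_names]
    data, labels = [], []
    for k, (onset_s, label) in enumerate(events):
        lab = _label_to_int(label)
        start = int(round(onset_s * hemo.fs))
        n = n_task if lab == 1 else n_rest
        if start < 0 or start + n > hemo.n_samples:
            raise ValueError(
                f"event {k} (onset {onset_s} s, label {label!r}): window of {n} samples "
                f"exceeds the recording ({hemo.n_samples} samples)")
        seg = np.concatenate([hemo.hbo[:, start : start + n], hemo.hbr[:, start : start + n]], axis=0)
        data.append(seg)
        labels.append(lab)
    n_ch = 2 * hemo.n_channels
    arr = np.stack(data) if data else np.empty((0, n_ch, n_task))
    return TrialSet(data=arr, labels=np.asarray(labels, dtype=int), subject_id=subject_id,
                    modality="fnirs-hemo", fs=hemo.fs, channel_names=names)


def paradigm_events(n_trials: int = 20, initial_rest_s: float = 10.0, cue_s: float = 1.0,
                    task_s: float = 15.0, rest_s: float = 20.0, rest_offset_s: float = 5.0):
    """Event table (onset_s, label) for the block paradigm: initial rest, then
    alternating cue→MI(task_s)→cue→rest(rest_s).  Rest windows are taken
    ``rest_offset_s`` after the rest cue to avoid task spillover."""
    events, t = [], initial_rest_s
    for _ in range(n_trials // 2):
        t += cue_s
        events.append((t, 1))
        t += task_s + cue_s
        events.append((t + rest_offset_s, 0))
        t += rest_s
    return events


# ----------------------------------------------------------- image generation
def _minmax_plane(p: np.ndarray) -> np.ndarray:
    lo, hi = p.min(), p.max()
    if hi - lo <= 0:
        return np.zeros_like(p)  # constant plane: defined as all-zero
    return (p - lo) / (hi - lo)


def _resize_plane(p: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    ah = interp_matrix(out_h, p.shape[-2])
    aw = interp_matrix(out_w, p.shape[-1])
    return ah @ p @ aw.T


def _parse_cmor(name: str) -> tuple:
    m = re.fullmatch(r"cmor([\d.]+)-([\d.]+)", name)
    if m is None:
        raise ValueError(f"unsupported wavelet {name!r}; expected 'cmorB-C'")
    return float(m.group(1)), float(m.group(2))


def morlet_cwt(x: np.ndarray, freqs_hz: np.ndarray, fs: float,
               bandwidth: float = 1.5, center: float = 1.0) -> np.ndarray:
    """Complex-Morlet continuous wavelet transform, computed in the frequency
    domain and vectorized over channels and scales.

    The analytic Morlet ``psi(t) = (pi*B)^-1/2 exp(-t^2/B) exp(2*pi*i*C*t)``
    has Fourier transform ``exp(-pi^2 B (f - C)^2)``; the coefficient at scale
    ``s = C*fs/f`` is ``ifft(fft(x) * sqrt(s) * conj(psi_hat(s f)))``.  Input
    ``x`` is [..., n_samples]; output is [..., n_freqs, n_samples].
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[-1]
    scales = center * fs / np.asarray(freqs_hz, dtype=np.float64)
    # zero-pad past the widest wavelet's support so the circular convolution
    # acts linearly (Gaussian envelope is negligible beyond ~4.5*s*sqrt(B));
    # padding is capped at 7n — scales wider than the whole record are
    # edge-dominated regardless of padding
    support = int(np.ceil(4.5 * scales.max() * np.sqrt(bandwidth)))
    nfft = next_fast_len(n + min(2 * support, 7 * n))
    xf = fft(x, nfft, axis=-1)
    f = np.fft.fftfreq(nfft)  # cycles per sample
    psi_hat = np.exp(-np.pi**2 * bandwidth * (scales[:, None] * f[None, :] - center) ** 2)
    w = ifft(xf[..., None, :] * (np.sqrt(scales)[:, None] * psi_hat), axis=-1)
    return w[..., :n]


def cwt_image(trial: np.ndarray, fs: float, wavelet: str = "cmor1.5-1.0",
              n_scales: int = 16, out_size: int = 64,
              fmin: float = 0.01, fmax: float = 0.2) -> TimeFreqImage:
    """Continuous-wavelet scalogram image of one fNIRS trial.

    ``trial`` is [n_channels, n_samples] (HbO₂+HbR planes stacked).  Scales
    are chosen so pseudo-frequencies log-span [fmin, fmax]; each channel
    plane is min-max normalized to [0, 1] and bilinearly resized to
    ``out_size²``.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    if trial.shape[-1] < 8:
        raise ValueError("cwt_image requires at least 8 samples per trial")
    if n_scales < 4:
        raise ValueError("n_scales must be >= 4")
    if not (0 < fmin < fmax < fs / 2):
        raise ValueError(f"pseudo-frequency range ({fmin}, {fmax}) must lie inside (0, fs/2)")
    bw, center = _parse_cmor(wavelet)
    freqs = np.geomspace(fmax, fmin, n_scales)  # descending: row 0 = highest frequency
    mag = np.abs(morlet_cwt(trial, freqs, fs, bandwidth=bw, center=center))  # (n_ch, S, T)
    planes = np.stack([_resize_plane(_minmax_plane(p), out_size, out_size) for p in mag])
    planes = np.clip(planes, 0.0, None)
    t = np.arange(trial.shape[-1]) / fs
    time_axis = interp_matrix(out_size, len(t)) @ t
    freq_axis = np.exp(interp_matrix(out_size, n_scales) @ np.log(freqs))
    return TimeFreqImage(pixels=planes, freq_axis=freq_axis, time_axis=time_axis,
                         source_modality="fnirs")


def stft_image(trial: np.ndarray, fs: float, window_s: float = 0.5,
               overlap_frac: float = 0.5, band=(4.0, 40.0),
               out_size: int = 64) -> TimeFreqImage:
    """STFT spectrogram image of one EEG trial, restricted to ``band`` Hz."""
    trial = np.atleast_2d(np.asarray(trial, dtype=np.float64))
    nperseg = int(round(window_s * fs))
    if nperseg < 8:
        raise ValueError("window_s * fs must be at least 8 samples")
    lo, hi = band
    if hi > fs / 2:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {fs / 2} Hz")
    hop = max(1, nperseg - int(round(overlap_frac * nperseg)))
    win = signal.windows.hann(nperseg, sym=False)
    sft = signal.ShortTimeFFT(win, hop=hop, fs=fs)
    S = sft.stft(trial, axis=-1)  # (n_ch, n_freq, n_frames)
    mag = np.abs(S)
    sel = (sft.f >= lo) & (sft.f <= hi)
    if not np.any(sel):
        raise ValueError("no STFT frequency bins inside the requested band")
    mag = mag[:, sel, :]
    freqs = sft.f[sel]
    frames = sft.t(trial.shape[-1])
    planes = np.stack([_resize_plane(_minmax_plane(p), out_size, out_size) for p in mag])
    planes = np.clip(planes, 0.0, None)
    time_axis = interp_matrix(out_size, len(frames)) @ frames
    freq_axis = interp_matrix(out_size, len(freqs)) @ freqs
    return TimeFreqImage(pixels=planes, freq_axis=freq_axis, time_axis=time_axis,
                         source_modality="eeg")


def trials_to_images(trials: TrialSet, out_size: int = 64, n_scales: int = 16,
                     wavelet: str = "cmor1.5-1.0", stft_window_s: float = 0.5,
                     stft_overlap: float = 0.5, eeg_band=(4.0, 40.0),
                     fnirs_band=(0.01, 0.2)) -> np.ndarray:
    """Stack per-trial time-frequency images into an NCHW float32 array."""
    out = []
    for k in range(trials.n_trials):
        if trials.modality == "eeg":
            img = stft_image(trials.data[k], trials.fs, window_s=stft_window_s,
                             overlap_frac=stft_overlap, band=eeg_band, out_size=out_size)
        else:
            img = cwt_image(trials.data[k], trials.fs, wavelet=wavelet, n_scales=n_scales,
                            out_size=out_size, fmin=fnirs_band[0], fmax=fnirs_band[1])
        out.append(img.pixels)
    return np.asarray(out, dtype=np.float32)
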