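"""Core data containers for the pipeline.

Conventions used throughout the package:

* fNIRS hemodynamic trial data stacks oxy- then deoxyhemoglobin planes along
  the channel axis: channels ``0..n-1`` are ΔHbO₂ ("CHxx_HbO") and channels
  ``n..2n-1`` are ΔHbR ("CHxx_HbR") for ``n`` optode channels.
* Raw optical trial data interleaves wavelengths per channel:
  ``CHxx_w730, CHxx_w850, ...``.
* Class labels are integers; for the target task MI = 1 (positive class) and
  rest = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigError",
    "TrialSet",
    "OpticalRecording",
    "ExtinctionMatrix",
    "HemoRecording",
    "TimeFreqImage",
    "default_extinction",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


MODALITIES = ("fnirs-hemo", "fnirs-raw", "eeg")


@dataclass
class TrialSet:
    """Labelled, equal-length trials: ``data[trial, channel, sample]``."""

    data: np.ndarray
    labels: np.ndarray
    subject_id: str
    modality: str
    fs: float
    channel_names: list | None = None
    class_names: tuple | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("TrialSet.data must be [n_trials, n_channels, n_samples]")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValueError("labels length must equal number of trials")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.data.size and not np.all(np.isfinite(self.data)):
            raise ValueError("TrialSet.data contains NaN or Inf")
        if self.channel_names is not None and len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class OpticalRecording:
    """Continuous raw dual-wavelength intensities: ``intensity[channel, wavelength, sample]``."""

    intensity: np.ndarray
    fs: float
    wavelengths: tuple = (730.0, 850.0)
    d_mm: float = 30.0
    dpf: tuple = (6.0, 6.0)
    channel_names: list | None = None

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
            raise ValueError("intensity must be [n_channels, 2 wavelengths, n_samples]")
        if np.any(self.intensity <= 0):
            raise ValueError("optical intensities must be strictly positive")
        if self.d_mm <= 0:
            raise ConfigError("d_mm: source-detector separation must be > 0")
        if len(self.dpf) != 2:
            raise ConfigError("dpf: one differential pathlength factor per wavelength")
        if self.channel_names is None:
            self.channel_names = [f"CH{i + 1:02d}" for i in range(self.intensity.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]


@dataclass
class ExtinctionMatrix:
    """Extinction coefficients ``eps[wavelength, chromophore]`` in 1/(mM·cm);
    chromophore order is (HbO₂, HbR)."""

    eps: np.ndarray

    def __post_init__(self):
        self.eps = np.asarray(self.eps, dtype=np.float64)
        if self.eps.shape != (2, 2):
            raise ValueError("eps must be a 2x2 matrix [wavelength x (HbO2, HbR)]")
        if np.linalg.cond(self.eps) >= 1e6:
            raise ValueError("extinction matrix is singular or ill-conditioned (cond >= 1e6)")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.eps)


def default_extinction() -> ExtinctionMatrix:
    """Typical molar extinction coefficients at 730 / 850 nm, 1/(mM·cm).

    Rounded literature values; the round-trip conversion is exact for any
    well-conditioned matrix, so these defaults only set a physiological scale.
    """
    return ExtinctionMatrix(np.array([
        [0.450, 1.0507],   # 730 nm: HbO2, HbR
        [1.1596, 0.7861],  # 850 nm: HbO2, HbR
    ]))


@dataclass
class HemoRecording:
    """Continuous ΔHbO₂ / ΔHbR channel time series (concentration change,
    mM under the chosen pathlength convention)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channel_names: list | None = None

    def __post_init__(self):
        self.hbo = np.asarray(self.hbo, dtype=np.float64)
        self.hbr = np.asarray(self.hbr, dtype=np.float64)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("hbo and hbr must have the same shape")
        if self.hbo.ndim != 2:
            raise ValueError("hbo/hbr must be [n_channels, n_samples]")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValueError("hemodynamic data contains NaN or Inf")
        if self.channel_names is None:
            self.channel_names = [f"CH{i + 1:02d}" for i in range(self.hbo.shape[0])]
        elif len(self.channel_names) != self.hbo.shape[0]:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]


@dataclass
class TimeFreqImage:
    """Per-trial multi-plane time-frequency image (nonnegative magnitudes)."""

    pixels: np.ndarray
    freq_axis: np.ndarray
    time_axis: np.ndarray
    source_modality: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be [image_channels, height, width]")
        if np.any(self.pixels < 0):
            raise ValueError("pixels must be nonnegative magnitudes")
        if len(self.freq_axis) != self.pixels.shape[1]:
            raise ValueError("freq_axis length must match image height")
        if len(self.time_axis) != self.pixels.shape[2]:
            raise ValueError("time_axis length must match image width")
        if self.source_modality not in ("eeg", "fnirs"):
            raise ValueError("source_modality must be 'eeg' or 'fnirs'")
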