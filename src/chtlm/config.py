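"""Validated pipeline configuration for the command-line interface.

The YAML layout mirrors the pipeline stages; unknown keys are rejected so a
typo cannot silently fall back to a default.  The resolved configuration is
re-serialized into every run directory.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .evaluation import PipelineConfig
from .synthetic import SynthConfig

__all__ = ["RunConfig", "SynthSection", "PipelineSection", "load_config", "ConfigFileError"]


class ConfigFileError(ValueError):
    """Configuration file failed validation; message names the field."""


class SynthSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects: int = 8
    trials_per_class: int = 10
    fs_fnirs: float = 11.0
    fs_eeg: float = 250.0
    n_channels_fnirs: int = 16
    n_channels_eeg: int = 22
    task_s: float = 15.0
    rest_s: float = 20.0
    eeg_trial_s: float = 4.0
    effect_amp: float = Field(1.0, ge=0)
    noise_sd: float = Field(1.0, gt=0)
    subject_gain_sd: float = Field(0.4, ge=0)
    subject_latency_sd: float = Field(1.5, ge=0)

    def to_synth(self, seed: int) -> SynthConfig:
        return SynthConfig(seed=seed, **self.model_dump())


class PipelineSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    target_variant: str = "tiny18"
    source_variant: str = "tiny34"
    image_size: int = Field(24, ge=8)
    n_scales: int = Field(14, ge=4)
    wavelet: str = "cmor1.5-1.0"
    fnirs_band: tuple[float, float] = (0.01, 0.2)
    eeg_band: tuple[float, float] = (4.0, 40.0)
    stft_window_s: float = 0.5
    stft_overlap: float = Field(0.5, ge=0, lt=1)
    beta: float = Field(0.5, ge=0)
    transfer_epochs: int = Field(8, ge=0)
    transfer_lr: float = Field(0.01, gt=0)
    source_epochs: int = Field(12, ge=0)
    source_lr: float = Field(0.01, gt=0)
    batch_size: int = Field(16, ge=1)
    alpha: float = Field(0.05, gt=0, le=1)
    sbelm_L: int = Field(100, ge=1)

    def to_pipeline(self, seed: int) -> PipelineConfig:
        d = self.model_dump()
        d["fnirs_band"] = tuple(d["fnirs_band"])
        d["eeg_band"] = tuple(d["eeg_band"])
        return PipelineConfig(seed=seed, **d)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    out_dir: str = "runs/chtlm"
    synth: SynthSection = SynthSection()
    pipeline: PipelineSection = PipelineSection()

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML config; ``overrides`` (CLI flags) win over
    file values.  Raises ConfigFileError naming the offending field."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigFileError("config file must contain a mapping")
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        section, _, leaf = key.partition(".")
        if leaf:
            data.setdefault(section, {})[leaf] = val
        else:
            data[key] = val
    try:
        return RunConfig.model_validate(data)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ConfigFileError(f"invalid configuration field '{loc}': {first['msg']}") from e
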