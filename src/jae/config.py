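"""Pipeline configuration: one YAML file holds every tunable constant.

The committed default configuration reproduces the clinical protocol's
constants — 250 Hz–10 kHz analysis band, 5 Hz motion low-pass, 400 ms
frames, ~4 s cycles, 0.5 decision threshold, 50 Hz IMU rate — at a
desk-scale 25 kHz audio rate (the band tops out at 10 kHz, so nothing the
pipeline measures is lost; set ``fs_audio: 100000`` to run at the original
acquisition rate).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .preprocessing import clamp_band
from .synthetic import ClassProfile, CohortSpec, followup_from

__all__ = ["PipelineConfig", "ConfigError", "load_config", "DEFAULT_CONFIG_YAML"]

DEFAULT_CONFIG_YAML = Path(__file__).parent / "data" / "default_config.yaml"


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class CohortConfig:
    n_jia: int = 25
    n_healthy: int = 18
    n_followup: int = 10
    cycles_per_recording: int = 10
    channels_per_subject: int = 4
    period_jitter: float = 0.02
    amplitude_jitter: float = 0.05
    noise_rms: float = 1.0
    jia_clicks_per_cycle: float = 6.0
    jia_click_amplitude: float = 8.0
    click_freq_range: tuple[float, float] = (2000.0, 8000.0)
    click_decay: float = 0.003
    followup_attenuation: float = 5.0


@dataclass
class PipelineConfig:
    """Validated configuration for every stage; serialized verbatim into
    every report this pipeline writes."""

    fs_audio: float = 25_000.0
    fs_motion: float = 50.0
    band: tuple[float, float] = (250.0, 10_000.0)
    lowpass_cutoff: float = 5.0
    frame_len: float = 0.4
    cycle_period: float = 4.0
    threshold: float = 0.5
    ridge: float = 1e-4
    perm_cap: int = 1000
    max_features: int = 20
    seed: int = 0
    registry: str = "default"
    auto_clamp_band: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fs_audio <= 0 or self.fs_motion <= 0:
            raise ConfigError("sampling rates must be positive")
        low, high = self.band
        if not 0 < low < high:
            raise ConfigError(f"need 0 < low < high in band, got {self.band}")
        if high >= self.fs_audio / 2:
            if not self.auto_clamp_band:
                raise ConfigError(
                    f"band upper edge {high:g} Hz violates the Nyquist limit "
                    f"{self.fs_audio / 2:g} Hz at fs_audio={self.fs_audio:g}")
            self.band = clamp_band(self.fs_audio, low, high)
        if int(round(self.frame_len * self.fs_audio)) < 8:
            raise ConfigError("frame_len x fs_audio must be >= 8 samples")
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigError("threshold must lie in [0, 1]")
        if self.ridge < 0:
            raise ConfigError("ridge must be >= 0")
        if self.perm_cap < 1 or self.max_features < 1:
            raise ConfigError("perm_cap and max_features must be >= 1")
        if self.cycle_period <= 0 or self.frame_len <= 0:
            raise ConfigError("cycle_period and frame_len must be positive")
        if self.fs_motion <= 2.0 / self.cycle_period:
            raise ConfigError("fs_motion must exceed 2 / cycle_period")
        c = self.cohort
        if c.n_followup > c.n_jia:
            raise ConfigError("n_followup must not exceed n_jia")
        if c.click_freq_range[1] >= self.fs_audio / 2:
            raise ConfigError(
                f"click_freq_range {c.click_freq_range} reaches Nyquist at "
                f"fs_audio={self.fs_audio:g}")

    def cohort_spec(self, seed: int | None = None) -> CohortSpec:
        c = self.cohort
        jia = ClassProfile(label="jia", noise_rms=c.noise_rms,
                           clicks_per_cycle=c.jia_clicks_per_cycle,
                           click_amplitude=c.jia_click_amplitude,
                           click_freq_range=tuple(c.click_freq_range),
                           click_decay=c.click_decay)
        healthy = ClassProfile(label="healthy", noise_rms=c.noise_rms)
        return CohortSpec(
            n_jia=c.n_jia, n_healthy=c.n_healthy, n_followup=c.n_followup,
            cycles_per_recording=c.cycles_per_recording,
            cycle_period=self.cycle_period,
            fs_audio=self.fs_audio, fs_motion=self.fs_motion,
            channels_per_subject=c.channels_per_subject,
            profiles={"healthy": healthy, "jia": jia},
            followup_profile=followup_from(jia, c.followup_attenuation),
            period_jitter=c.period_jitter,
            amplitude_jitter=c.amplitude_jitter,
            seed=self.seed if seed is None else seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["cohort"]["click_freq_range"] = list(self.cohort.click_freq_range)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        cohort_data = dict(data.pop("cohort", {}) or {})
        known_c = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = set(cohort_data) - known_c
        if bad:
            raise ConfigError(f"unknown cohort keys: {sorted(bad)}")
        if "click_freq_range" in cohort_data:
            cohort_data["click_freq_range"] = tuple(cohort_data["click_freq_range"])
        known = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "band" in data:
            data["band"] = tuple(data["band"])
        return cls(cohort=CohortConfig(**cohort_data), **data)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> PipelineConfig:
    """Load YAML config (the committed defaults when ``path`` is None) and
    apply flat key overrides."""
    source = Path(path) if path is not None else DEFAULT_CONFIG_YAML
    with open(source) as fh:
        data = yaml.safe_load(fh) or {}
    for key, val in (overrides or {}).items():
        if val is not None:
            data[key] = val
    return PipelineConfig.from_dict(data)
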