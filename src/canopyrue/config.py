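"""Run configuration: YAML schema, validation and defaults.

A single YAML file with ``weather``, ``canopy``, ``photosynthesis`` and
``run`` sections configures the whole pipeline.  Defaults reproduce the
reference simulation setup: 6.5 plants m-2, 900 mg leaf N per plant,
alpha = 0.05, theta = 0.8, K_diff = 0.7, 10 canopy layers, DOY 200-260,
LAI in {3..7} and leaf-area peak depths in {0.3..0.7}.  Unknown keys are
rejected rather than silently ignored.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .structure import LIA_MEANS_DEG

__all__ = [
    "WeatherSection",
    "CanopySection",
    "PhotosynthesisSection",
    "RunSection",
    "RunConfig",
    "load_config",
    "dump_config",
]

_DEFAULT_HOURS = [6.5 + i for i in range(12)]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class WeatherSection(_Section):
    latitude: float = Field(39.93, ge=-90, le=90)
    doy_start: int = Field(200, ge=1, le=366)
    doy_end: int = Field(260, ge=1, le=366)
    transmissivity: float = Field(0.70, gt=0, le=1)
    diffuse_fraction: float = Field(0.23, ge=0, le=1)
    extraterrestrial_par: float = Field(2900.0, gt=0)
    hours: list[float] = Field(default_factory=lambda: list(_DEFAULT_HOURS))
    cloud_noise_sd: float = Field(0.0, ge=0)
    seed: int | None = None

    @model_validator(mode="after")
    def _season_ok(self):
        if self.doy_end < self.doy_start:
            raise ValueError("doy_end must not precede doy_start")
        return self


class CanopySection(_Section):
    lia_means: list[float] = Field(default_factory=lambda: list(LIA_MEANS_DEG))
    lia_concentration: float = Field(11.0, gt=2)
    n_distributions: int = Field(28, ge=1)
    #: None selects the leaf-area-like Beta(a, 2) nitrogen family; a number
    #: selects the fixed shape-parameter-sum alternative
    n_concentration: float | None = None
    n_mode_min: float = Field(0.24, gt=0, lt=1)
    n_mode_max: float = Field(0.78, gt=0, lt=1)
    lai_levels: list[float] = Field(default_factory=lambda: [3.0, 4.0, 5.0, 6.0, 7.0])
    zm_fractions: list[float] = Field(default_factory=lambda: [0.3, 0.4, 0.5, 0.6, 0.7])
    lnc_tot_mg: float = Field(900.0, gt=0)
    density: float = Field(6.5, gt=0)
    n_layers: int = Field(10, ge=2)

    @model_validator(mode="after")
    def _factors_ok(self):
        if not self.lia_means or not self.lai_levels or not self.zm_fractions:
            raise ValueError("factor lists must be non-empty")
        if any(not 0 < m < 90 for m in self.lia_means):
            raise ValueError("lia_means must lie in (0, 90) degrees")
        if any(not 0 < z < 1 for z in self.zm_fractions):
            raise ValueError("zm_fractions must lie in (0, 1)")
        if any(l <= 0 for l in self.lai_levels):
            raise ValueError("lai_levels must be positive")
        return self


class PhotosynthesisSection(_Section):
    alpha: float = Field(0.05, gt=0)
    theta: float = Field(0.8, ge=0, le=1)
    k_diff: float = Field(0.7, gt=0)


class RunSection(_Section):
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"


class RunConfig(_Section):
    schema_version: int = 1
    weather: WeatherSection = WeatherSection()
    canopy: CanopySection = CanopySection()
    photosynthesis: PhotosynthesisSection = PhotosynthesisSection()
    run: RunSection = RunSection()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; an absent/empty file gives defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path: str | Path | None = None) -> str:
    """Serialize the resolved config to YAML (round-trips to an equal config)."""
    text = yaml.safe_dump(config.model_dump(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
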