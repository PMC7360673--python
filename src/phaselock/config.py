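"""Run configuration: schema, validation and defaults.

Configs are YAML or JSON. Validation is exhaustive — every schema violation
is reported, not just the first — and unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Raised with the full list of schema violations."""


class BandConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    lo: float = Field(gt=0)
    hi: float = Field(gt=0)

    @model_validator(mode="after")
    def _order(self):
        if self.lo >= self.hi:
            raise ValueError(f"band {self.name!r}: lo must be below hi")
        return self


class SeedConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    laterality: Literal["left", "right", "bilateral"] = "bilateral"
    source_indices: list[int] | None = None
    centers: list[list[float]] | None = None
    radius: float = 15.0

    @model_validator(mode="after")
    def _one_of(self):
        if (self.source_indices is None) == (self.centers is None):
            raise ValueError(
                f"seed {self.name!r}: give exactly one of source_indices or centers"
            )
        return self


class CBPTSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cluster_forming_alpha: float = Field(default=0.05, gt=0, lt=1)
    n_permutations: int = 5000
    t_variant: Literal["pooled", "welch"] = "pooled"
    max_stat: Literal["both_signs", "per_sign"] = "both_signs"

    @model_validator(mode="after")
    def _floor(self):
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be at least 100")
        return self


class SimulateSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_robust: int = Field(default=34, ge=2)
    n_frail: int = Field(default=20, ge=2)
    grid_shape: list[int] = Field(default=[5, 5, 4])
    grid_spacing: float = Field(default=10.0, gt=0)
    epochs_mean_robust: float = 81.0
    epochs_sd_robust: float = 13.1
    epochs_mean_frail: float = 77.5
    epochs_sd_frail: float = 12.1
    min_epochs: int = Field(default=20, ge=1)
    sigma_obs: float = Field(default=0.2, ge=0)
    effect_band: str = "upper_beta"
    effect_rho_robust: float = Field(default=0.45, ge=0, lt=1)
    effect_delta_rho: float = Field(default=0.15, ge=0)
    effect_seed_indices: list[int] | None = None
    effect_target_indices: list[int] | None = None
    null_cohort: bool = False


class RunConfig(BaseModel):
    """Fully-defaulted, validated pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    cohort_dir: str | None = None  # existing cohort (manifest.tsv + grid.h5)
    simulate: SimulateSection | None = None
    bands: list[BandConfig] = Field(
        default=[
            BandConfig(name="alpha_mu", lo=8.0, hi=13.0),
            BandConfig(name="low_beta", lo=12.0, hi=20.0),
            BandConfig(name="upper_beta", lo=20.0, hi=30.0),
        ]
    )
    epoch_len: float = Field(default=4.0, gt=0)
    pad: float = Field(default=2.0, ge=0)
    max_epochs: int | None = None
    seeds: list[SeedConfig] = Field(default_factory=list)
    rsn_file: str | None = None
    use_default_rsns: bool = False
    pair_policy: Literal["all_pairs", "between_spheres"] = "all_pairs"
    cbpt: CBPTSection = Field(default_factory=CBPTSection)
    clinical: bool = False
    output_dir: str = "phaselock_out"
    rng_seed: int = 0

    @model_validator(mode="after")
    def _checks(self):
        if (self.cohort_dir is None) == (self.simulate is None):
            raise ValueError("give exactly one of cohort_dir or simulate")
        if not self.seeds and self.rsn_file is None and not self.use_default_rsns and not self.clinical:
            raise ValueError(
                "no analysis enabled: configure seeds, an RSN file, "
                "use_default_rsns or clinical"
            )
        if self.cohort_dir is not None and not Path(self.cohort_dir).exists():
            raise ValueError(f"cohort_dir {self.cohort_dir!r} does not exist")
        if self.rsn_file is not None and not Path(self.rsn_file).exists():
            raise ValueError(f"rsn_file {self.rsn_file!r} does not exist")
        return self


def _format_errors(err: ValidationError) -> str:
    lines = []
    for e in err.errors():
        loc = ".".join(str(p) for p in e["loc"]) or "<root>"
        lines.append(f"  {loc}: {e['msg']}")
    return "invalid configuration:\n" + "\n".join(lines)


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate raw YAML/JSON text (or an already-parsed mapping).

    Raises :class:`ConfigError` listing every violation.
    """
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError(f"config is not valid YAML/JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_errors(exc)) from exc


def load_config(path) -> RunConfig:
    return validate_config(Path(path).read_text())
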