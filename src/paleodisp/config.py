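"""Run configuration: a single schema-validated YAML/JSON document.

Unknown keys are rejected so typos fail before any computation; all
dispersal defaults are pre-filled with the standard parameter set.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .exceptions import ConfigurationError
from .solver import DispersalParams

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DomainSpec(_Strict):
    lon_min: float = -15.0
    lon_max: float = 49.0
    lat_min: float = 20.0
    lat_max: float = 60.0
    resolution: float = 0.5

    @model_validator(mode="after")
    def _ordered(self):
        if self.lon_min >= self.lon_max or self.lat_min >= self.lat_max:
            raise ValueError("domain ranges must be ordered")
        return self


class ParamSpec(_Strict):
    rho_c_max: float = 5.0
    eps: float = 0.4
    eta: float = 2.5
    alpha: float = 20.0
    gamma: float = 0.1
    d_min: float = 10.0
    d_max: float = 100.0
    kappa: float = 1.0
    kappa_l: float = 1.0
    kappa_sigma: float = 0.1
    r_max: float = 0.01
    dt_days: float = 10.0
    arrival_threshold: float = 0.4
    snapshot_interval_yr: float = 10.0

    def to_params(self) -> DispersalParams:
        return DispersalParams(**self.model_dump())


class InitialSpec(_Strict):
    center_lon: float = 35.0
    center_lat: float = 32.5
    spread_km: float = 150.0
    total_population: float = 5000.0


class TimeSpec(_Strict):
    start_ka: float = 45.0
    end_ka: float = 25.0

    @model_validator(mode="after")
    def _forward(self):
        if self.start_ka <= self.end_ka:
            raise ValueError("start_ka must be older (larger) than end_ka")
        return self


class NicheSpec(_Strict):
    block_size: float | None = None
    pseudo_absence_option: int = Field(default=3, ge=1, le=3)
    n_members: int = Field(default=1000, ge=1)
    train_fraction: float = Field(default=0.8, gt=0.0, lt=1.0)
    ridge: float = Field(default=1e-6, ge=0.0)


class EnsembleSpecConfig(_Strict):
    levels: int = Field(default=5, ge=1)
    rho_c_max_range: tuple[float, float] | None = None
    alpha_range: tuple[float, float] | None = None
    d_scale_range: tuple[float, float] | None = None


class PathSpec(_Strict):
    output_dir: str = "output"
    sites_csv: str | None = None
    isotope_csv: str | None = None
    stack_nc: str | None = None
    bioclim_dir: str | None = None


class SyntheticSpec(_Strict):
    enabled: bool = True
    site_target: int = 120
    period_yr: float = 1000.0
    isotope_shape: str = "square"


class RunConfig(_Strict):
    domain: DomainSpec = DomainSpec()
    params: ParamSpec = ParamSpec()
    initial: InitialSpec = InitialSpec()
    times: TimeSpec = TimeSpec()
    niche: NicheSpec = NicheSpec()
    ensemble: EnsembleSpecConfig = EnsembleSpecConfig()
    paths: PathSpec = PathSpec()
    synthetic: SyntheticSpec = SyntheticSpec()
    seed: int = 0
    log_level: str = "INFO"


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:
        raise ConfigurationError(f"invalid configuration {path}: {exc}") from exc


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonicalised configuration."""
    canon = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
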