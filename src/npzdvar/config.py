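"""Run configuration: YAML loading with strict validation and full defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml

from .model import EcoParameters

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass
class DomainConfig:
    resolution_arcmin: float = 4.0
    layer_thicknesses: list = field(default_factory=lambda: [5.0, 10.0, 10.0, 20.0, 25.0, 25.0])


@dataclass
class ForcingConfig:
    days: float = 30.0
    step_hours: float = 6.0
    max_speed: float = 0.1
    horizontal_diffusivity: float = 50.0
    vertical_diffusivity: float = 1e-4
    irradiance_peak: float = 100.0
    sst_mean: float = 22.0


@dataclass
class ModelConfig:
    # ecological parameters (defaults: the standard coastal NPZD set)
    Vm: float = 1.0
    Gm: float = 0.5
    Dp: float = 0.1
    Dz: float = 0.2
    e: float = 0.05
    AQ10: float = 2.08
    BQ10: float = 3.10
    gamma: float = 0.75
    theta: float = 0.03
    Kext: float = 1.0
    Io: float = 100.0
    wp: float = 0.73
    wd: float = 1.00
    Ks: float = 1.0
    f_ivlev: float = 0.2
    # run controls
    initial_N: float = 6.0
    initial_Z: float = 0.1
    initial_D: float = 0.1
    spin_up_days: float = 10.0
    bio_substeps: int = 1
    n_surface_source: float = 0.0

    def eco_parameters(self) -> EcoParameters:
        names = {f.name for f in fields(EcoParameters)}
        return EcoParameters(**{k: v for k, v in asdict(self).items() if k in names})


@dataclass
class IpsConfig:
    method: str = "spline"
    spacing: int = 5
    radius: float | None = None  # Cressman; default 2.5 * spacing

    def __post_init__(self) -> None:
        if self.method not in ("spline", "cressman"):
            raise ConfigError(f"ips.method must be 'spline' or 'cressman', got {self.method!r}")


@dataclass
class AssimilationConfig:
    max_iterations: int = 100
    ncf_threshold: float = 5e-4
    alpha0: float | None = None  # default: 2% of control range
    step_growth: float = 1.2
    max_halvings: int = 5
    normalize_gradient: bool = True


@dataclass
class ExperimentConfig:
    truth: str = "IE1"
    ie1_peak: float = 3.0
    ie1_floor: float = 0.5
    ie2_p_ref: float = 1.5
    ie2_slope: float = 0.2


@dataclass
class RunConfig:
    domain: DomainConfig = field(default_factory=DomainConfig)
    forcing: ForcingConfig = field(default_factory=ForcingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    ips: IpsConfig = field(default_factory=IpsConfig)
    assimilation: AssimilationConfig = field(default_factory=AssimilationConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    seed: int = 0
    output_dir: str = "output"

    def to_dict(self) -> dict:
        return asdict(self)


_BLOCKS = {
    "domain": DomainConfig,
    "forcing": ForcingConfig,
    "model": ModelConfig,
    "ips": IpsConfig,
    "assimilation": AssimilationConfig,
    "experiment": ExperimentConfig,
}


def _build_block(cls, data: dict, block: str):
    allowed = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{block}]: {', '.join(sorted(unknown))}")
    kwargs = {}
    for key, value in data.items():
        expected = allowed[key].type
        if value is None and "None" not in str(expected):
            raise ConfigError(f"[{block}] {key} must not be null")
        if isinstance(value, str) and expected in ("float", "int"):
            raise ConfigError(f"[{block}] {key} must be numeric, got {value!r}")
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{block}] block: {exc}") from exc


def load_config(path) -> RunConfig:
    """Read and validate a YAML run configuration.

    An empty file yields pure defaults.  Unknown keys anywhere are
    rejected with the offending key named.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"configuration file not found: {p}")
    raw = yaml.safe_load(p.read_text())
    return config_from_dict(raw or {})


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    scalars = {"seed", "output_dir"}
    unknown = set(raw) - set(_BLOCKS) - scalars
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = raw.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"[{name}] must be a mapping")
        kwargs[name] = _build_block(cls, block, name)
    if "seed" in raw:
        if not isinstance(raw["seed"], int) or isinstance(raw["seed"], bool):
            raise ConfigError("seed must be an integer")
        kwargs["seed"] = raw["seed"]
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    return RunConfig(**kwargs)
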