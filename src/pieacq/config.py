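"""Experiment configuration: YAML/JSON loading, schema validation with
unknown-key rejection, and a validation report listing applied defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .acquisition import AcquisitionConfig
from .mixture import MixtureConfig


class SchemaError(ValueError):
    """Raised when a config file has unknown keys or ill-typed sections."""


@dataclass
class CampaignConfig:
    mode: str = "compare"          # "dda" | "pie" | "compare"
    n_replicates: int = 3          # DDA replicates
    n_iterations: int = 3          # PIE iterations
    fraction_mode: bool = False
    fraction_dimension: str = "hilic"

    def validate(self) -> None:
        if self.mode not in ("dda", "pie", "compare"):
            raise ValueError(f"unknown campaign mode {self.mode!r}")
        if self.n_replicates < 1 or self.n_iterations < 1:
            raise ValueError("replicate/iteration counts must be >= 1")
        if self.fraction_dimension not in ("hilic", "scx"):
            raise ValueError("fraction_dimension must be 'hilic' or 'scx'")


@dataclass
class ReportConfig:
    noise_sd: float = 0.2          # reporter log2 noise
    make_plot: bool = False

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class ExperimentConfig:
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    campaign: CampaignConfig = field(default_factory=CampaignConfig)
    report: ReportConfig = field(default_factory=ReportConfig)
    seed: int = 0

    def validate(self) -> None:
        self.mixture.validate()
        self.acquisition.validate()
        self.campaign.validate()
        self.report.validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def canonical_json(self) -> str:
        def _default(o):
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))
        return json.dumps(self.to_dict(), sort_keys=True, default=_default)


_SECTION_TYPES = {
    "mixture": MixtureConfig,
    "acquisition": AcquisitionConfig,
    "campaign": CampaignConfig,
    "report": ReportConfig,
}

_TUPLE_FIELDS = {"rt_sigma_range", "protein_length_range"}


def _build_section(cls, data: dict, section: str, applied_defaults: list[str]):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise SchemaError(
            f"unknown key(s) in section {section!r}: {', '.join(sorted(unknown))}"
        )
    kwargs = {}
    for name, f in known.items():
        if name in data:
            value = data[name]
            if name in _TUPLE_FIELDS and isinstance(value, list):
                value = tuple(value)
            if name == "charge_distribution" and isinstance(value, dict):
                value = {int(k): float(v) for k, v in value.items()}
            kwargs[name] = value
        else:
            applied_defaults.append(f"{section}.{name}")
    return cls(**kwargs)


def config_from_dict(data: dict) -> tuple[ExperimentConfig, list[str]]:
    """Build an :class:`ExperimentConfig` from a plain mapping.

    Unknown keys anywhere raise :class:`SchemaError`. Returns the config and
    the list of dotted paths where defaults were applied.
    """
    if not isinstance(data, dict):
        raise SchemaError("config root must be a mapping")
    unknown = set(data) - set(_SECTION_TYPES) - {"seed"}
    if unknown:
        raise SchemaError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    applied: list[str] = []
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        payload = data.get(name)
        if payload is None:
            applied.append(name)
            sections[name] = cls()
        elif isinstance(payload, dict):
            sections[name] = _build_section(cls, payload, name, applied)
        else:
            raise SchemaError(f"section {name!r} must be a mapping")
    seed = data.get("seed", 0)
    if "seed" not in data:
        applied.append("seed")
    return ExperimentConfig(seed=int(seed), **sections), applied


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML (or JSON) experiment config file."""
    cfg, _ = config_from_dict(yaml.safe_load(Path(path).read_text()) or {})
    cfg.validate()
    return cfg


@dataclass
class ValidationReport:
    defaults_applied: list[str]
    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_config(path: str | Path) -> ValidationReport:
    """Validate a config file without running anything.

    Lists every default applied and every constraint violation found; never
    raises for constraint violations (only for unreadable files).
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        cfg, applied = config_from_dict(data)
    except SchemaError as err:
        return ValidationReport([], [str(err)])
    violations = []
    for section in ("mixture", "acquisition", "campaign", "report"):
        try:
            getattr(cfg, section).validate()
        except ValueError as err:
            violations.append(f"{section}: {err}")
    return ValidationReport(applied, violations)
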