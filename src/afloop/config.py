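"""Run configuration: a strict, schema-versioned YAML/JSON config.

A minimal config only needs ``master_seed``; every other key has a
documented default.  Unknown keys (top-level or nested) are rejected by
name, so typos fail loudly before any simulation starts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationTargets
from .virtual_cohort import CohortSpec

__all__ = ["RunConfig", "CalibrationSettings", "load_config", "config_to_dict"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CalibrationSettings:
    """Calibration windows and iteration budget (edv_target is per patient)."""

    sys_range: tuple[float, float] = (90.0, 140.0)
    dia_range: tuple[float, float] = (60.0, 90.0)
    ef_min: float = 50.0
    edv_tolerance: float = 0.05
    max_iter: int = 30

    def targets_for(self, edv_target: float) -> CalibrationTargets:
        return CalibrationTargets(
            sys_range=tuple(self.sys_range),
            dia_range=tuple(self.dia_range),
            ef_min=self.ef_min,
            edv_target=edv_target,
            edv_tolerance=self.edv_tolerance,
        )


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a full trial run."""

    master_seed: int
    schema_version: int = SCHEMA_VERSION
    n_patients: int = 10
    physiological_bpm: float = 61.0
    rapid_bpm: float = 94.0
    rr_cv: float = 0.24
    rr_bounds: tuple[float, float] = (0.3, 2.0)
    av_delay_s: float = 0.16
    dt_s: float = 1e-3
    output_dir: str = "results"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version} "
                f"(expected {SCHEMA_VERSION})"
            )
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.physiological_bpm <= 0 or self.rapid_bpm <= 0:
            raise ValueError("rate levels must be > 0 bpm")
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be >= 0")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.av_delay_s < 0:
            raise ValueError("av_delay_s must be >= 0")


def _build_dataclass(cls, data: dict, context: str):
    field_info = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_info)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} in {context}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = field_info[name].type
        if isinstance(value, dict):
            nested = {"cohort": CohortSpec, "calibration": CalibrationSettings}.get(
                name
            )
            if nested is None:
                raise ValueError(f"key {name!r} in {context} does not take a mapping")
            value = _build_dataclass(nested, value, f"{context}.{name}")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root in {path} must be a mapping")
    if "master_seed" not in data:
        raise ValueError("config must set master_seed")
    return _build_dataclass(RunConfig, data, str(path))


def config_to_dict(config: RunConfig) -> dict:
    """Effective configuration as plain JSON/YAML-serialisable types."""

    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {
                f.name: convert(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            }
        if isinstance(obj, tuple):
            return [convert(v) for v in obj]
        return obj

    return convert(config)
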