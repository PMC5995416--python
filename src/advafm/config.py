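"""Pipeline configuration: one seed, per-stage parameter blocks, YAML IO."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .morphometry import MorphometryParams
from .synthetic import CohortConfig, FibrilFieldSpec

__all__ = ["DMTParams", "PipelineConfig", "load_config"]


@dataclass
class DMTParams:
    """Contact-mechanics fitting parameters."""

    R_nm: float = 8.0
    nu: float = 0.0
    fit_window: tuple[float, float] = (0.1, 0.9)
    E_ref_known_MPa: float | None = None


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; all randomness flows from ``seed``."""

    seed: int = 0
    morphometry: MorphometryParams = field(default_factory=MorphometryParams)
    dmt: DMTParams = field(default_factory=DMTParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    image_size_px: int = 256
    nm_per_px: float = 2000.0 / 256.0

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise KeyError(f"unknown {cls.__name__} field: {key}")
        ftype = fields[key].type
        if isinstance(value, dict) and key in _NESTED:
            value = _build(_NESTED[key], value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    "morphometry": MorphometryParams,
    "dmt": DMTParams,
    "cohort": CohortConfig,
    "field_low": FibrilFieldSpec,
    "field_high": FibrilFieldSpec,
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from YAML (unknown keys are an error)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(PipelineConfig, data)
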