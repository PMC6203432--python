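"""Run configuration: YAML-backed, fully serializable, published-constant
defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import DynamicsConstants


@dataclass
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    environment: dict = field(default_factory=lambda: {
        "kind": "rectangle", "width_cm": 150.0, "height_cm": 150.0})
    test_environments: list = field(default_factory=list)
    familiarize_s: float = 3600.0
    test_s: float = 1800.0
    settle_s: float = 2.0
    n_modules: int = 5
    module_indices: list | None = None  # defaults to 1..n_modules
    sheet_size: int = 128
    g1: float = 0.45
    orientation_deg: float = -7.5
    template_wavelength: float = 14.68
    rate_based: bool = False
    record_grid_per_module: int = 30
    n_place: int = 64
    n_place_afferents: int = 500
    border_depth_cm: float = 12.0
    border_amplitude: float = 0.1
    noise_per: str = "step"
    seeds: dict = field(default_factory=lambda: {
        "network": 0, "path": 1, "spiking": 2})
    dynamics: dict = field(default_factory=dict)  # DynamicsConstants overrides

    def constants(self) -> DynamicsConstants:
        base = asdict(DynamicsConstants())
        unknown = set(self.dynamics) - set(base)
        if unknown:
            raise ValueError(f"unknown dynamics keys: {sorted(unknown)}")
        base.update(self.dynamics)
        return DynamicsConstants(**base)

    def network_config(self):
        from .engine import NetworkConfig

        return NetworkConfig(
            n_modules=self.n_modules,
            module_indices=tuple(self.module_indices) if self.module_indices else None,
            sheet_size=self.sheet_size, g1=self.g1,
            orientation_deg=self.orientation_deg,
            template_wavelength=self.template_wavelength,
            n_place=self.n_place, n_place_afferents=self.n_place_afferents,
            border_depth_cm=self.border_depth_cm,
            border_amplitude=self.border_amplitude,
            rate_based=self.rate_based,
            record_grid_per_module=self.record_grid_per_module,
            settle_s=self.settle_s, const=self.constants())

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    """Load a YAML run config; unspecified fields take the model defaults and
    unknown keys raise with the offending name."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    allowed = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.constants()  # validate dynamics overrides eagerly
    return cfg
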