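"""Run configuration: a validated, YAML-loadable description of an end-to-end
simulation (geometry, fiber count, arrays, grid resolution, membrane and pulse
settings, experiments, seed)."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cable import MembraneSpec
from .geometry import GeometryConfig

__all__ = ["RunConfig", "load_config"]

KNOWN_EXPERIMENTS = ("thresholds", "degeneration", "robustness", "matrix",
                     "specificity")
KNOWN_ARRAYS = ("pmST", "pmSV", "lwST", "lwSV")


@dataclass
class RunConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    n_fibers: int = 25
    arrays: tuple[str, ...] = KNOWN_ARRAYS
    orientation_mode: str = "default"
    voxel_spacing_um: float = 60.0
    membrane: MembraneSpec = field(default_factory=MembraneSpec)
    pulse_duration_ms: float = 0.05
    polarities: tuple[str, ...] = ("cathodic", "anodic")
    conditions: tuple[str, ...] = ("healthy", "thin_dendrite", "no_dendrite")
    experiments: tuple[str, ...] = ("thresholds", "degeneration")
    dt_ms: float = 1e-3
    solver_rtol: float = 1e-8
    seed: int = 0

    def validate(self) -> None:
        self.geometry.validate()
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        for a in self.arrays:
            if a not in KNOWN_ARRAYS:
                raise ValueError(f"unknown array tag {a!r}")
        for e in self.experiments:
            if e not in KNOWN_EXPERIMENTS:
                raise ValueError(f"unknown experiment {e!r}")
        if self.voxel_spacing_um <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.orientation_mode not in ("default", "alternative"):
            raise ValueError("orientation_mode must be default|alternative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _tupleize(cfg_cls, data: dict) -> dict:
    fields = {f.name: f for f in dataclasses.fields(cfg_cls)}
    out = {}
    for k, v in data.items():
        if k not in fields:
            raise ValueError(f"unknown config key {k!r} for {cfg_cls.__name__}")
        if isinstance(v, list):
            v = tuple(v)
        out[k] = v
    return out


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; omitted keys keep their defaults."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    geo = GeometryConfig(**_tupleize(GeometryConfig, doc.pop("geometry", {})))
    mem = MembraneSpec(**_tupleize(MembraneSpec, doc.pop("membrane", {})))
    cfg = RunConfig(geometry=geo, membrane=mem, **_tupleize(RunConfig, doc))
    cfg.validate()
    return cfg
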