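"""Pipeline configuration.

A flat, typed configuration covering every stage; unknown keys are
rejected so typos never silently fall back to defaults, and every run
archives its resolved configuration next to the outputs.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    # phantom
    seed: int = 0
    n_teeth: int = 4
    arch_radius: float = 24.0
    interproximal_gap: float = 0.5
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    noise_sd: float = 30.0
    streak_amplitude: float = 0.0
    # optical scanning
    view_count: int = 8
    point_spacing: float = 0.15
    scan_noise_sd: float = 0.0
    mesh_pitch: float = 0.3
    # registration / merging
    merge_tolerance: float = 0.05
    icp_max_iter: int = 50
    icp_tol: float = 1e-6
    icp_reject_dist: float = 5.0
    # crown segmentation
    curvature_radius: float = 2.0
    reconstruction_pitch: float = 0.3
    margin_seeds: int = 8
    # CBCT alignment / threshold sweep
    tau_grid: tuple[float, ...] = (-200.0, 0.0, 250.0, 500.0, 750.0, 1000.0)
    delta_eps: float = 1.0
    # DRLSE
    drlse_mu: float = 0.2
    drlse_lambda: float = 5.0
    drlse_alpha: float = 0.5
    drlse_sigma: float = 1.5
    drlse_timestep: float = 1.0
    drlse_iterations: int = 20
    drlse_first_slice_iterations: int = 100
    # fusion
    seam_band: float = 0.5
    # stage toggles
    do_scan: bool = True
    do_crown_segmentation: bool = True
    do_cbct: bool = True
    do_fusion: bool = True
    do_bone: bool = True
    # io
    output_dir: str = "orthomodel_output"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.n_teeth < 1:
            raise ConfigError("n_teeth must be >= 1")
        if min(cfg.spacing) <= 0:
            raise ConfigError("spacing must be positive")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must hold a mapping")
        for k, v in data.items():
            if isinstance(v, list):
                data[k] = tuple(v)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def write_resolved(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = directory / "resolved_config.yaml"
        out.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return out
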