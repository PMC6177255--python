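"""Run configuration: YAML file + CLI overrides, manifest writing."""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__


@dataclass
class RunConfig:
    """All tunables of a pipeline run; CLI flags override file values."""

    # imaging
    threshold_method: str = "otsu"
    fixed_value: float | None = None
    min_object_px: int = 64
    min_hole_px: int = 64
    # radial bands
    inner_frac: float = 0.25
    outer_frac: float = 0.75
    variant: str = "density_normalized"
    # AFM
    tip_radius: float = 2.5
    poisson: float = 0.5
    spring_constant: float = 0.05
    # expression design
    housekeeping: str = "18S"
    reference_group: str = "pure_uninduced"
    pure_control: str = "pure_uninduced"
    mixed_control: str = "mixed_uninduced"
    alpha: float = 0.05
    # run plumbing
    seed: int = 0
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text()) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a mapping")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)} - {"extras"}
        extras = {k: data.pop(k) for k in list(data) if k not in known}
        cfg = cls(**data, extras=extras)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 < self.inner_frac < self.outer_frac < 1.0:
            raise ValueError("require 0 < inner_frac < outer_frac < 1")
        if self.tip_radius <= 0:
            raise ValueError("tip_radius must be > 0")
        if not 0 <= self.poisson < 1:
            raise ValueError("poisson must lie in [0, 1)")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


def write_manifest(out_dir: str | Path, command: str, config: RunConfig,
                   notes: dict | None = None) -> Path:
    """Write a JSON run manifest (config echo, version, seed, timestamp)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "mosaiq_version": __version__,
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": dataclasses.asdict(config),
        **(notes or {}),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
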