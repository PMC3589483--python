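"""Run-configuration loading and validation (YAML, schema-checked)."""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .energetics import GridSpec


@dataclass
class RunConfig:
    """Validated settings shared by the CLI subcommands.

    Unknown keys are rejected rather than ignored, so a typo in a config
    file fails loudly before any computation starts.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    criterion_mode: str = "distance_angle"
    distance_cutoff: float = 3.0
    angle_cutoff: float = 20.0
    radius_overrides: dict = field(default_factory=dict)
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.criterion_mode not in ("distance_angle", "radius_sum"):
            raise ValueError(f"bad criterion_mode {self.criterion_mode!r}")
        if self.verbosity not in (0, 1, 2):
            raise ValueError("verbosity must be 0, 1 or 2")
        for el, r in self.radius_overrides.items():
            if r <= 0:
                raise ValueError(f"radius override for {el} must be > 0")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    grid_known = {f.name for f in fields(GridSpec)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "grid" in raw:
        g = raw["grid"] or {}
        bad = set(g) - grid_known
        if bad:
            raise ValueError(f"unknown grid keys: {sorted(bad)}")
        raw = dict(raw, grid=GridSpec(**g))
    return RunConfig(**raw)
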