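"""Run configuration: a flat, human-editable YAML file.

A configuration has five optional blocks — ``parameters``, ``scenario``,
``sweeps``, ``synthetic`` and ``output`` — each a mapping of known keys.
Every key has a default, so an empty file is a complete, valid
configuration (the default model parameter set and calibrated media).
Unknown keys are rejected with field-level messages, and the fully
resolved configuration is echoed next to the outputs so every run is
self-describing.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .parameters import ModelParameters
from .simulate import (
    DEFAULT_T_END,
    DEFAULT_TOTAL_INOCULUM,
    MEDIA,
    RATIO_GRID_FULL,
    RATIO_GRID_MIXED,
)

__all__ = ["RunConfig", "ScenarioBlock", "SweepBlock", "SynthBlock", "OutputBlock",
           "load_config", "dump_config", "write_config"]


@dataclass(frozen=True)
class ScenarioBlock:
    total_inoculum: float = DEFAULT_TOTAL_INOCULUM
    t_end: float = DEFAULT_T_END
    solver_rel_tol: float = 1e-8
    solver_abs_tol: float = 1e-10
    n_output_points: int = 501
    media: dict = field(
        default_factory=lambda: {m: {"A0": a, "B0": b} for m, (a, b) in MEDIA.items()}
    )

    def __post_init__(self) -> None:
        for medium, nutrients in self.media.items():
            unknown = set(nutrients) - {"A0", "B0"}
            if unknown:
                raise ValueError(f"scenario.media.{medium}: unknown keys {sorted(unknown)}")
            for key, value in nutrients.items():
                if value < 0:
                    raise ValueError(f"scenario.media.{medium}.{key} must be >= 0; got {value}")


@dataclass(frozen=True)
class SweepBlock:
    ratio_grid: tuple = RATIO_GRID_FULL
    chi_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)
    chi_init_fracs: tuple = RATIO_GRID_MIXED

    def __post_init__(self) -> None:
        if any(not 0 <= q <= 1 for q in self.ratio_grid):
            raise ValueError("sweeps.ratio_grid values must lie in [0, 1]")
        if any(not 0 <= x <= 2 for x in self.chi_grid):
            raise ValueError("sweeps.chi_grid values must lie in [0, 2]")


@dataclass(frozen=True)
class SynthBlock:
    seed: int = 0
    n_replicates: int = 3
    noise_cv: float = 0.1
    times_h: tuple = (6.0, 12.0, 24.0, 48.0)
    cells_per_unit: float = 1e8
    gain: float = 1.0
    count_noise: bool = True

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("synthetic.noise_cv must be >= 0")
        if self.n_replicates < 0:
            raise ValueError("synthetic.n_replicates must be >= 0")


@dataclass(frozen=True)
class OutputBlock:
    directory: str = "protcoop_out"
    log_level: str = "INFO"


_BLOCKS = {
    "parameters": ModelParameters,
    "scenario": ScenarioBlock,
    "sweeps": SweepBlock,
    "synthetic": SynthBlock,
    "output": OutputBlock,
}


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration for one pipeline run."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    scenario: ScenarioBlock = field(default_factory=ScenarioBlock)
    sweeps: SweepBlock = field(default_factory=SweepBlock)
    synthetic: SynthBlock = field(default_factory=SynthBlock)
    output: OutputBlock = field(default_factory=OutputBlock)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for name in _BLOCKS:
            block = asdict(getattr(self, name))
            out[name] = {
                k: list(v) if isinstance(v, tuple) else v for k, v in block.items()
            }
        return out


def _build_block(name: str, cls, raw: Mapping[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"config block {name!r}: unknown keys {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as err:
        raise ValueError(f"config block {name!r}: {err}") from err


def from_dict(raw: Mapping[str, Any] | None) -> RunConfig:
    """Validate a raw mapping and materialize all defaults."""
    raw = dict(raw or {})
    unknown = set(raw) - set(_BLOCKS)
    if unknown:
        raise ValueError(
            f"unknown top-level config keys {sorted(unknown)}; expected {sorted(_BLOCKS)}"
        )
    blocks = {
        name: _build_block(name, cls, raw.get(name) or {})
        for name, cls in _BLOCKS.items()
    }
    return RunConfig(**blocks)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML configuration file.

    An empty file (or one with empty blocks) resolves to all defaults.
    """
    text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    if raw is not None and not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping, got {type(raw).__name__}")
    return from_dict(raw)


def dump_config(config: RunConfig) -> str:
    """Serialize a resolved configuration as YAML."""
    return yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=None)


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(dump_config(config), encoding="utf-8", newline="\n")
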