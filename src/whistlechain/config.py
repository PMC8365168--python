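"""Typed configuration for the measurement pipeline.

A single YAML file drives every stage; unknown keys are rejected so that a
typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segmentation import SegmentationConfig
from .synthetic_data import ChainPlan, GeneratorParams, constant_plan, drifting_plan


class ConfigError(ValueError):
    """Configuration file contains an unknown or invalid key."""


@dataclass
class MeasureConfig:
    """Per-measure tunables (units noted per field).

    bin_width: chi-square bin width in semitones.
    k_max / n_runs: Gaussian-mixture search depth and number of restarts.
    slide_threshold: semitone magnitude below which a target move is level.
    n_shuffles: permutations for the interval compression ratio.
    block_threshold: DDTW merge threshold for building blocks.
    resample_len: DDTW resampling length (points).
    ddtw_smooth_window: pre-DDTW smoothing window (track samples).
    entropy_base: logarithm base of the entropy measure (2 = bits).
    """

    bin_width: float = 1.0
    k_max: int = 10
    n_runs: int = 100
    slide_threshold: float = 1.0
    n_shuffles: int = 100
    block_threshold: float = 0.08
    resample_len: int = 25
    ddtw_smooth_window: int = 25
    entropy_base: float = 2.0


@dataclass
class TrendConfig:
    min_generations: int = 3


@dataclass
class SimulateConfig:
    """What to simulate: a named preset or explicit start/end parameters."""

    preset: str = "drifting"           # drifting | constant
    n_generations: int = 10
    n_chains: int = 4
    start: dict = field(default_factory=dict)
    end: dict = field(default_factory=dict)

    def plan(self) -> ChainPlan:
        if self.start or self.end:
            start = _build(GeneratorParams, self.start, "simulate.start")
            end_kwargs = {**self.start, **self.end}
            end = _build(GeneratorParams, end_kwargs, "simulate.end")
            return ChainPlan(start_params=start, end_params=end,
                             n_generations=self.n_generations,
                             n_chains=self.n_chains)
        if self.preset == "drifting":
            return drifting_plan(self.n_generations, self.n_chains)
        if self.preset == "constant":
            return constant_plan(n_generations=self.n_generations,
                                 n_chains=self.n_chains)
        raise ConfigError(f"unknown simulate.preset {self.preset!r}")


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "out"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    measures: MeasureConfig = field(default_factory=MeasureConfig)
    trends: TrendConfig = field(default_factory=TrendConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build(cls, data: dict, where: str):
    """Instantiate a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{where}: expected a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


_SECTIONS = {
    "segmentation": SegmentationConfig,
    "measures": MeasureConfig,
    "trends": TrendConfig,
    "simulate": SimulateConfig,
}


def load_config(path=None) -> PipelineConfig:
    """Load a pipeline configuration from YAML (None -> all defaults)."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    scalar_keys = {"seed", "input_dir", "output_dir"}
    unknown = set(raw) - scalar_keys - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {k: raw[k] for k in scalar_keys if k in raw}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    return PipelineConfig(**kwargs)
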