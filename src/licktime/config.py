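"""Run configuration: every tunable parameter of every stage, in one
structured document. Unknown keys are rejected before any computation, and
the pipeline echoes every parameter into the run log exactly once."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .synthetic import OptoConfig, SimConfig
from .types import InvalidConfigError


@dataclass
class BehaviorParams:
    bout_break_s: float = 1.0
    isolation_s: float = 2.0
    psth_bin_s: float = 0.1
    psth_window: tuple[float, float] = (-2.0, 4.0)
    rebound_window_s: float = 2.0


@dataclass
class ClassificationParams:
    noise_floor_uv: float = 30.0
    channel_threshold: int = 7
    optotag_window_ms: float = 10.0
    optotag_alpha: float = 0.05


@dataclass
class EntrainmentParams:
    fdr: float = 0.05
    kernel_width: float = 0.3
    kernel: str = "wrapped_gaussian"
    grid_size: int = 360


@dataclass
class AlignedParams:
    bin_s: float = 0.1
    first_lick_window: tuple[float, float] = (-1.0, 0.5)
    term_window_s: float = 0.3
    term_baseline: tuple[float, float] = (-5.0, -1.0)
    term_sd_cutoff: float = 2.0
    baseline_exclusion_s: float = 2.0
    min_events_per_context: int = 5


@dataclass
class CalciumParams:
    sd_cutoff: float = 3.0
    min_dendrites_per_region: int = 5
    min_bouts_for_onset: int = 20
    peri_water_s: float = 0.5


@dataclass
class RunConfig:
    out_dir: str = "results/run"
    bundle_dir: Optional[str] = None        # read this bundle instead of simulating
    simulate: Optional[SimConfig] = field(default_factory=SimConfig)
    opto: Optional[OptoConfig] = None
    n_units: int = 12
    n_dendrites: int = 10
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    classification: ClassificationParams = field(
        default_factory=ClassificationParams
    )
    entrainment: EntrainmentParams = field(default_factory=EntrainmentParams)
    aligned: AlignedParams = field(default_factory=AlignedParams)
    calcium: CalciumParams = field(default_factory=CalciumParams)
    report: bool = True
    seed: int = 0


_NESTED = {
    "simulate": SimConfig,
    "opto": OptoConfig,
    "behavior": BehaviorParams,
    "classification": ClassificationParams,
    "entrainment": EntrainmentParams,
    "aligned": AlignedParams,
    "calcium": CalciumParams,
}


def _build(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise InvalidConfigError(
            f"unknown key(s) {sorted(unknown)} in config section {path!r}"
        )
    # tuples arrive from YAML as lists
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(doc)


def config_from_dict(doc: dict) -> RunConfig:
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise InvalidConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for key, val in doc.items():
        if key in _NESTED:
            if val is None:
                kwargs[key] = None
            else:
                kwargs[key] = _build(_NESTED[key], dict(val), key)
        else:
            kwargs[key] = val
    cfg = RunConfig(**kwargs)
    if cfg.simulate is not None:
        cfg.simulate.seed = cfg.seed
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
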