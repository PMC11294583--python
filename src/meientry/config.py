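"""Run configuration: schema, validation, defaults and (de)serialization.

A run configuration has four blocks — ``model`` (rate constants, signals,
baseline state, simulation grid, observable map), ``cohort`` (synthetic
generator conditions), ``analysis`` (clustering and peak-window settings)
— plus a master ``seed`` and an ``output_dir``.  Files are YAML (JSON is
valid YAML); unknown keys are rejected with their full key path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import (
    DEFAULT_BASELINE,
    DEFAULT_OBSERVABLE_MATRIX,
    ModelParameters,
    ModelState,
    SignalSpec,
)
from .synth import CohortConfig

__all__ = ["AnalysisConfig", "RunConfig", "load_config", "save_config", "stage_seed"]


class ConfigError(ValueError):
    """Schema violation, reported with the offending key path."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings of the trace-analysis stage."""

    k: int = 6
    replicates: int = 10
    max_iter: int = 10000
    rim11_window: int = 60
    other_window: int = 40
    cluster_frames: int = 80
    mi_min_rise: float = 10.0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError("analysis.k must be >= 2")
        for name in ("replicates", "max_iter", "rim11_window", "other_window",
                     "cluster_frames"):
            if getattr(self, name) < 1:
                raise ConfigError(f"analysis.{name} must be >= 1")
        if self.mi_min_rise <= 0:
            raise ConfigError("analysis.mi_min_rise must be > 0")


@dataclass(frozen=True)
class RunConfig:
    """Complete, validated configuration of an end-to-end run."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    signals: tuple[SignalSpec, SignalSpec, SignalSpec] = field(
        default_factory=lambda: (SignalSpec(), SignalSpec(), SignalSpec()))
    baseline: ModelState = DEFAULT_BASELINE
    t_end: float = 24.0
    dt: float = 0.2
    observable_matrix: tuple = tuple(map(tuple, DEFAULT_OBSERVABLE_MATRIX))
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    output_dir: str = "results"

    def observable_array(self) -> np.ndarray:
        return np.asarray(self.observable_matrix, dtype=float)


def _build(cls, data: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key {path}.{sorted(unknown)[0]}")
    try:
        return cls(**data)
    except ConfigError:
        raise
    except TypeError as exc:
        raise ConfigError(f"invalid block {path}: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"invalid value under {path}: {exc}") from exc


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON configuration; missing keys use defaults.

    An empty file yields the all-defaults configuration.
    """
    if data is None:
        if path is None:
            data = {}
        else:
            text = Path(path).read_text()
            data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")

    top_valid = {"model", "cohort", "analysis", "seed", "output_dir"}
    unknown = set(data) - top_valid
    if unknown:
        raise ConfigError(f"unknown key {sorted(unknown)[0]}")

    kwargs: dict = {}
    model_block = dict(data.get("model") or {})
    model_valid = {"parameters", "signals", "baseline", "simulation", "observable_map"}
    unknown = set(model_block) - model_valid
    if unknown:
        raise ConfigError(f"unknown key model.{sorted(unknown)[0]}")
    if "parameters" in model_block:
        kwargs["parameters"] = _build(
            ModelParameters, dict(model_block["parameters"]), "model.parameters")
    if "baseline" in model_block:
        kwargs["baseline"] = _build(
            ModelState, dict(model_block["baseline"]), "model.baseline")
    if "signals" in model_block:
        sig_block = model_block["signals"]
        sigs = []
        for name in ("S1", "S2", "S3"):
            entry = dict(sig_block.get(name) or {})
            sigs.append(_build(SignalSpec, entry, f"model.signals.{name}"))
        extra = set(sig_block) - {"S1", "S2", "S3"}
        if extra:
            raise ConfigError(f"unknown key model.signals.{sorted(extra)[0]}")
        kwargs["signals"] = tuple(sigs)
    if "simulation" in model_block:
        sim = dict(model_block["simulation"])
        extra = set(sim) - {"t_end", "dt"}
        if extra:
            raise ConfigError(f"unknown key model.simulation.{sorted(extra)[0]}")
        if "t_end" in sim:
            kwargs["t_end"] = float(sim["t_end"])
        if "dt" in sim:
            kwargs["dt"] = float(sim["dt"])
        if kwargs.get("t_end", 24.0) <= 0 or kwargs.get("dt", 0.2) <= 0:
            raise ConfigError("model.simulation.t_end and .dt must be positive")
    if "observable_map" in model_block:
        mat = np.asarray(model_block["observable_map"], dtype=float)
        if mat.shape != (3, 7):
            raise ConfigError("model.observable_map must be a 3x7 matrix")
        kwargs["observable_matrix"] = tuple(map(tuple, mat))

    if "cohort" in data:
        kwargs["cohort"] = _build(CohortConfig, dict(data["cohort"] or {}), "cohort")
    if "analysis" in data:
        kwargs["analysis"] = _build(
            AnalysisConfig, dict(data["analysis"] or {}), "analysis")
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "output_dir" in data:
        kwargs["output_dir"] = str(data["output_dir"])
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a RunConfig to YAML (lossless round trip via load_config)."""
    params = {
        f.name: getattr(config.parameters, f.name)
        for f in dataclasses.fields(ModelParameters)
        if getattr(config.parameters, f.name) is not None
        and f.name != "closure_derived"
    }
    data = {
        "model": {
            "parameters": params,
            "signals": {
                name: dataclasses.asdict(spec)
                for name, spec in zip(("S1", "S2", "S3"), config.signals)
            },
            "baseline": dataclasses.asdict(config.baseline),
            "simulation": {"t_end": config.t_end, "dt": config.dt},
            "observable_map": [[float(v) for v in row]
                               for row in config.observable_matrix],
        },
        "cohort": dataclasses.asdict(config.cohort),
        "analysis": dataclasses.asdict(config.analysis),
        "seed": config.seed,
        "output_dir": config.output_dir,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of (master seed, stage name)."""
    h = np.uint64(1469598103934665603)
    for b in f"{master_seed}:{stage}".encode():
        h = np.uint64((int(h) ^ b) * 1099511628211 % (1 << 64))
    return int(h % np.uint64(2**31 - 1))
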