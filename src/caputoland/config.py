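"""Run configuration: schema-validated settings with execution profiles.

Two profiles are first class: ``full`` (population 50, 700 generations,
h = 0.05 ms — the full calibration budget, hours-scale) and ``ci``
(population 16, 40 generations, h = 1 ms — a desk-scale budget that keeps
the whole pipeline in minutes while preserving every pipeline property).
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .calibration import GAConfig, StabilityCriteria
from .fde import SolverConfig
from .land import STATE_NAMES

__all__ = ["RunConfig", "load_config", "PROFILES", "write_text_atomic", "config_hash"]

PROFILES = {
    "full": {"population_size": 50, "max_generations": 700, "h": 5e-5},
    "ci": {"population_size": 16, "max_generations": 40, "h": 1e-3},
}


class SolverSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    h: Optional[float] = None  # filled from profile when absent
    memory_length: Optional[int] = None
    divergence_bound: float = 1e3
    corrector_iterations: int = 1
    initial_derivative: Literal["rhs", "zero"] = "rhs"


class GASettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mse_tolerance: float = 1e-5
    population_size: Optional[int] = None
    max_generations: Optional[int] = None
    stall_generations: int = 50
    lower_bounds_stretch: Optional[list[float]] = None
    upper_bounds_stretch: Optional[list[float]] = None
    lower_bounds_release: Optional[list[float]] = None
    upper_bounds_release: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check_bounds(self):
        for kind in ("stretch", "release"):
            lb = getattr(self, f"lower_bounds_{kind}")
            ub = getattr(self, f"upper_bounds_{kind}")
            for v in (lb, ub):
                if v is not None and len(v) != 6:
                    raise ValueError(f"{kind} bounds must have 6 entries")
            if lb is not None and ub is not None:
                bad = [STATE_NAMES[i] for i in range(6) if lb[i] > ub[i]]
                if bad:
                    raise ValueError(f"lower bound exceeds upper bound for state(s) {bad}")
        return self


class StabilitySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_oscillations: int = 2
    min_settling: float = 0.5
    prominence_frac: float = 0.02


class NoiseSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma: float = 0.02
    rho: float = 0.8


class PathsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    params: Optional[str] = None
    protocol: Optional[str] = None
    data: Optional[str] = None
    output: str = "cls_output"


class RunConfig(BaseModel):
    """Fully validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    profile: Literal["full", "ci"] = "full"
    seed: int = 0
    stretch_fraction: float = 0.01
    paths: PathsSettings = Field(default_factory=PathsSettings)
    solver: SolverSettings = Field(default_factory=SolverSettings)
    ga: GASettings = Field(default_factory=GASettings)
    stability: StabilitySettings = Field(default_factory=StabilitySettings)
    noise: NoiseSettings = Field(default_factory=NoiseSettings)

    def solver_config(self, t0: float = 0.0, t_end: float = 2.0) -> SolverConfig:
        h = self.solver.h if self.solver.h is not None else PROFILES[self.profile]["h"]
        return SolverConfig(
            h=h,
            t0=t0,
            t_end=t_end,
            memory_length=self.solver.memory_length,
            divergence_bound=self.solver.divergence_bound,
            corrector_iterations=self.solver.corrector_iterations,
            initial_derivative=self.solver.initial_derivative,
        )

    def ga_config(self) -> GAConfig:
        prof = PROFILES[self.profile]
        kwargs = dict(
            mse_tolerance=self.ga.mse_tolerance,
            population_size=self.ga.population_size or prof["population_size"],
            max_generations=self.ga.max_generations or prof["max_generations"],
            stall_generations=self.ga.stall_generations,
            rng_seed=self.seed,
        )
        if self.ga.lower_bounds_stretch is not None:
            kwargs["lower_bounds"] = tuple(self.ga.lower_bounds_stretch)
        if self.ga.upper_bounds_stretch is not None:
            kwargs["upper_bounds"] = tuple(self.ga.upper_bounds_stretch)
        return GAConfig(**kwargs)

    def stability_criteria(self) -> StabilityCriteria:
        return StabilityCriteria(
            max_oscillations=self.stability.max_oscillations,
            min_settling=self.stability.min_settling,
            prominence_frac=self.stability.prominence_frac,
        )


def load_config(path: "str | Path | None") -> RunConfig:
    """Load and validate a JSON or YAML config file; empty/None gives defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    if not text.strip():
        return RunConfig()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_text_atomic(path: "str | Path", text: str) -> None:
    """Write a file atomically (temp file + rename); no partial outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + f".tmp{os.getpid()}")
    tmp.write_text(text)
    tmp.replace(path)
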