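"""Model configuration: defaults, validation, and YAML/JSON round-trip.

The default parameter set: sensory and decision
populations of 1000 LIF neurons, memory and comparison populations of 1500;
24 represented dimensions for the visual code, 4 for the comparison stage
and 1 for the decision; intercepts Uniform(0.01, 0.1) for sensory/memory
(so those neurons are silent without input), Uniform(0.01, 1) for
comparison and Uniform(-1, 1) for decision; membrane constants
tau_rc = 20 ms and tau_ref = 2 ms; and calcium kinetics U = 0.2,
tau_D = 0.2 s, tau_F = 1.5 s on the memory population's recurrent
connections.  Everything is overridable from a config file; unknown keys
are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .neural_core import LIFParams
from .stsp import STSPParams


@dataclass
class PopulationConfig:
    n: int
    dims: int
    intercept_low: float
    intercept_high: float
    max_rate_low: float = 200.0
    max_rate_high: float = 400.0

    def lif_params(self) -> LIFParams:
        return LIFParams(intercept_low=self.intercept_low,
                         intercept_high=self.intercept_high,
                         max_rate_low=self.max_rate_low,
                         max_rate_high=self.max_rate_high)


@dataclass
class ModelConfig:
    """All structural and kinetic parameters of the two-module model."""

    sensory: PopulationConfig = field(default_factory=lambda: PopulationConfig(1000, 24, 0.01, 0.1))
    memory: PopulationConfig = field(default_factory=lambda: PopulationConfig(1500, 24, 0.01, 0.1))
    comparison: PopulationConfig = field(default_factory=lambda: PopulationConfig(1500, 4, 0.01, 1.0))
    decision: PopulationConfig = field(default_factory=lambda: PopulationConfig(1000, 1, -1.0, 1.0))
    stsp: STSPParams = field(default_factory=STSPParams)
    dt: float = 0.001  # s
    n_gabors: int = 1000
    basis_step_deg: float = 1.0
    tau_feedforward: float = 0.01  # s, all non-recurrent connections
    tau_recurrent_fast: float = 0.005  # s, AMPA-like recurrent component
    tau_recurrent_slow: float = 0.1  # s, NMDA-like recurrent component
    recurrent_slow_weight: float = 1.0  # weight of the slow component
    memory_decoder_reg: float = 0.03  # ridge for the recurrent identity decode
    reactivation_amplitude: float = 0.02  # membrane-voltage units per ms
    reactivation_duration_ms: int = 20
    noise_std: float = 0.0  # background current noise (projection units)
    decoder_reg: float = 0.1
    n_modules: int = 2

    def validate(self) -> "ModelConfig":
        if self.dt <= 0:
            raise ValueError("dt: must be positive")
        if not (0 < self.stsp.U <= 1):
            raise ValueError("stsp.U: must lie in (0, 1]")
        if self.stsp.tau_D <= 0:
            raise ValueError("stsp.tau_D: must be positive")
        if self.stsp.tau_F <= 0:
            raise ValueError("stsp.tau_F: must be positive")
        if (self.tau_feedforward < 0 or self.tau_recurrent_fast < 0
                or self.tau_recurrent_slow < 0):
            raise ValueError("synaptic time constants must be >= 0")
        if self.recurrent_slow_weight < 0:
            raise ValueError("recurrent_slow_weight: must be >= 0")
        if self.reactivation_duration_ms < 0:
            raise ValueError("reactivation_duration_ms: must be >= 0")
        if self.n_gabors < self.sensory.dims:
            raise ValueError("n_gabors: must be at least the represented dimensionality")
        if self.sensory.n != self.n_gabors:
            raise ValueError("sensory.n must equal n_gabors (one Gabor encoder per neuron)")
        if self.memory.dims != self.sensory.dims:
            raise ValueError("sensory and memory dimensions must match")
        if self.comparison.dims != 4 or self.decision.dims != 1:
            raise ValueError("comparison must represent 4 dims and decision 1")
        if self.noise_std < 0:
            raise ValueError("noise_std: must be >= 0")
        for name in ("sensory", "memory", "comparison", "decision"):
            getattr(self, name).lif_params()  # raises on bad ranges
        return self


def _to_dict(obj) -> dict:
    return dataclasses.asdict(obj)


def _from_dict(cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"{path or 'config'}: expected a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{path or 'config'}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = f"{path}.{name}" if path else name
        if isinstance(value, dict):
            target = {"sensory": PopulationConfig, "memory": PopulationConfig,
                      "comparison": PopulationConfig, "decision": PopulationConfig,
                      "stsp": STSPParams}.get(name)
            if target is None:
                raise ValueError(f"{sub}: unexpected mapping")
            kwargs[name] = _from_dict(target, value, sub)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path or 'config'}: {exc}") from exc


def load_config(path) -> ModelConfig:
    """Read a YAML (or JSON) config file; absent keys take the defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    cfg = _from_dict(ModelConfig, data)
    try:
        cfg.validate()
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return cfg


def save_config(cfg: ModelConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_to_dict(cfg), f, sort_keys=False)


def config_to_dict(cfg: ModelConfig) -> dict:
    return _to_dict(cfg)


def config_from_dict(data: dict) -> ModelConfig:
    return _from_dict(ModelConfig, data).validate()
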