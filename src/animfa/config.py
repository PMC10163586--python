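"""Structured plain-text run configuration (YAML).

A config has up to five sections::

    parameters: {tau: 3.0, zeta: 1.0, xi: 1.0}      # or delta/beta raw rates
    responses:  {builtin: linear_breaking}           # or f_br/f_cr expressions
    analysis:   {horizon: 200.0, grid: [201, 201], tol: 1.0e-6, ...}
    output:     {dir: out}
    seed: 0

Parsing round-trips: write -> read -> write is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Optional

import yaml

from .dynamics import ModelParameters, rescale_parameters
from .responses import FunctionalResponsePair, builtin_pair, pair_from_expressions

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """A malformed or inconsistent run configuration."""


@dataclasses.dataclass
class RunConfig:
    parameters: dict
    responses: dict
    analysis: dict = dataclasses.field(default_factory=dict)
    output: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def model_parameters(self) -> ModelParameters:
        p = dict(self.parameters)
        try:
            if "delta" in p or "beta" in p:
                return rescale_parameters(
                    float(p["delta"]), float(p["beta"]),
                    float(p.get("zeta", 1.0)), float(p.get("xi", 1.0)),
                )
            return ModelParameters(
                tau=float(p["tau"]),
                zeta=float(p.get("zeta", 1.0)),
                xi=float(p.get("xi", 1.0)),
                epsilon=float(p["epsilon"]) if "epsilon" in p else None,
            )
        except KeyError as exc:
            raise ConfigError(f"parameters section missing field {exc}") from None
        except ValueError as exc:
            raise ConfigError(str(exc)) from None

    def response_pair(self) -> FunctionalResponsePair:
        r = dict(self.responses)
        try:
            if "builtin" in r:
                return builtin_pair(str(r["builtin"]))
            return pair_from_expressions(
                str(r["f_br"]), str(r["f_cr"]), name=str(r.get("name", "custom"))
            )
        except KeyError as exc:
            raise ConfigError(f"responses section missing field {exc}") from None
        except ValueError as exc:
            raise ConfigError(str(exc)) from None

    def to_dict(self) -> dict:
        return {
            "parameters": dict(self.parameters),
            "responses": dict(self.responses),
            "analysis": dict(self.analysis),
            "output": dict(self.output),
            "seed": int(self.seed),
        }

    def digest(self) -> str:
        return hashlib.sha256(dump_config(self).encode()).hexdigest()[:16]


def _validate(cfg: RunConfig) -> RunConfig:
    for key, value in cfg.analysis.items():
        if key.endswith("tol") and not (isinstance(value, (int, float)) and value > 0):
            raise ConfigError(f"analysis tolerance {key!r} must be positive, got {value}")
    cfg.model_parameters()
    cfg.response_pair()
    return cfg


def load_config(path) -> RunConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from None
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    unknown = set(raw) - {"parameters", "responses", "analysis", "output", "seed"}
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    try:
        cfg = RunConfig(
            parameters=dict(raw.get("parameters", {})),
            responses=dict(raw.get("responses", {})),
            analysis=dict(raw.get("analysis", {})),
            output=dict(raw.get("output", {})),
            seed=int(raw.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"malformed config {path}: {exc}") from None
    return _validate(cfg)


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True, default_flow_style=False)
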