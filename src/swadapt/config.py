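"""Scenario configuration files (YAML/JSON) and run manifests."""

from __future__ import annotations

import getpass
import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Union

import yaml

from .adapt import AdaptationPolicy
from .designs import AllocationMatrix, Cohort, TrialDesign
from .lmm import VarianceComponents
from .simulate import ScenarioConfig


class ConfigError(ValueError):
    """Schema violation in a scenario configuration, with field context."""


_SCHEMA = {
    "name": str,
    "design": {"clusters": int, "periods": int, "m": int, "cohort": str,
               "allocation": str, "interim_periods": list,
               "alpha": float, "beta": float, "delta": float},
    "variance": {"sigma2_c": float, "sigma2_pi": float,
                 "sigma2_s": float, "sigma2_e": float},
    "policy": {"w": float, "eta": float, "gamma": float, "restriction": str},
    "simulation": {"theta": float, "n_reps": int, "seed": int,
                   "analysis_mode": str},
}

_DEFAULTS: dict[str, dict[str, Any]] = {
    "design": {"alpha": 0.05, "beta": 0.2, "delta": 0.0, "interim_periods": [],
               "cohort": "cross_sectional"},
    "variance": {"sigma2_c": 0.0, "sigma2_pi": 0.0, "sigma2_s": 0.0},
    "policy": {"w": 0.5, "eta": 0.0, "gamma": 2.5, "restriction": "none"},
    "simulation": {"theta": 0.0, "n_reps": 10_000, "seed": 1,
                   "analysis_mode": "collapsed"},
}

_REQUIRED = {"design": ("clusters", "periods", "m", "allocation"),
             "variance": ("sigma2_e",)}


def _check_section(section: str, data: dict, schema: dict) -> dict:
    if not isinstance(data, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    unknown = set(data) - set(schema)
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    for key in _REQUIRED.get(section, ()):
        if key not in data:
            raise ConfigError(f"missing required key {section}.{key}")
    out = dict(_DEFAULTS.get(section, {}))
    for key, value in data.items():
        want = schema[key]
        if want is float and isinstance(value, (int, float)) and not isinstance(value, bool):
            value = float(value)
        elif not isinstance(value, want) or isinstance(value, bool):
            raise ConfigError(
                f"{section}.{key} must be {want.__name__}, got {type(value).__name__}")
        out[key] = value
    return out


def config_from_dict(raw: dict) -> ScenarioConfig:
    if not isinstance(raw, dict):
        raise ConfigError("top level of a scenario config must be a mapping")
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    for sec in ("design", "variance"):
        if sec not in raw:
            raise ConfigError(f"missing required section {sec!r}")
    name = raw.get("name", "")
    d = _check_section("design", raw["design"], _SCHEMA["design"])
    v = _check_section("variance", raw["variance"], _SCHEMA["variance"])
    p = _check_section("policy", raw.get("policy", {}), _SCHEMA["policy"])
    s = _check_section("simulation", raw.get("simulation", {}), _SCHEMA["simulation"])
    try:
        design = TrialDesign(
            C=d["clusters"], P=d["periods"], m=d["m"], cohort=Cohort(d["cohort"]),
            X_init=AllocationMatrix.from_string(d["allocation"]),
            interim_periods=tuple(d["interim_periods"]),
            alpha=d["alpha"], beta=d["beta"], delta=d["delta"], name=name)
        vc = VarianceComponents(sigma2_c=v["sigma2_c"], sigma2_pi=v["sigma2_pi"],
                                sigma2_s=v["sigma2_s"], sigma2_e=v["sigma2_e"])
        policy = AdaptationPolicy(w=p["w"], eta=p["eta"], gamma=p["gamma"],
                                  restriction=p["restriction"])
        return ScenarioConfig(design=design, vc=vc, policy=policy,
                              theta_true=s["theta"], n_reps=s["n_reps"],
                              seed=s["seed"], analysis_mode=s["analysis_mode"],
                              name=name)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def parse_config(path: Union[str, Path]) -> ScenarioConfig:
    """Read and validate a YAML (or JSON) scenario configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_to_dict(config: ScenarioConfig) -> dict:
    """Serialize to the schema accepted by :func:`config_from_dict` (round-trips)."""
    d = config.design
    return {
        "name": config.name,
        "design": {"clusters": d.C, "periods": d.P, "m": d.m,
                   "cohort": d.cohort.value, "allocation": d.X_init.to_string(),
                   "interim_periods": list(d.interim_periods),
                   "alpha": d.alpha, "beta": d.beta, "delta": d.delta},
        "variance": {"sigma2_c": config.vc.sigma2_c, "sigma2_pi": config.vc.sigma2_pi,
                     "sigma2_s": config.vc.sigma2_s, "sigma2_e": config.vc.sigma2_e},
        "policy": {"w": config.policy.w, "eta": config.policy.eta,
                   "gamma": config.policy.gamma,
                   "restriction": config.policy.restriction},
        "simulation": {"theta": config.theta_true, "n_reps": config.n_reps,
                       "seed": config.seed, "analysis_mode": config.analysis_mode},
    }


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility sidecar attached to every CLI output file."""

    config_digest: str
    seed: int
    version: str
    timestamp: str
    command: str

    @classmethod
    def create(cls, config_dict: dict, seed: int) -> "RunManifest":
        from . import __version__
        digest = hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()).hexdigest()[:16]
        return cls(config_digest=digest, seed=seed, version=__version__,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
                   command=" ".join(sys.argv))

    def write(self, out_path: Union[str, Path]) -> Path:
        side = Path(str(out_path) + ".manifest.json")
        side.write_text(json.dumps(self.__dict__, indent=2) + "\n")
        return side
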