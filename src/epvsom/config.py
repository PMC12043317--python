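"""Declarative experiment configuration (YAML/JSON) with strict validation.

A config has a ``circuit`` block (Table-style weight names ``wEE..wSS`` plus
optional ``alpha``/``beta``/``tau``), an ``experiment`` name, an
experiment-specific ``params`` block, a ``seed``, and a ``provenance`` map
tagging values as printed constants (``PUBLISHED``), reconstructed unprinted
inputs (``RECONSTRUCTED``) or package defaults (``DEFAULT``).  Unknown keys
anywhere are rejected before any computation runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .circuit_model import WEIGHT_INDEX, CircuitParams

EXPERIMENTS = ("simulate", "scan", "vectorfield", "sweep", "noisy", "tuning")

_CIRCUIT_KEYS = set(WEIGHT_INDEX) | {"alpha", "beta", "tau"}
_TOP_KEYS = {"circuit", "experiment", "params", "seed", "provenance", "name"}

_PARAM_KEYS = {
    "simulate": {
        "rates", "dI_som", "dI_stim", "t_mod", "t_stim", "dt", "T", "r0",
    },
    "scan": {"rE_axis", "rP_axis", "rS", "dI_stim"},
    "vectorfield": {"rE_axis", "rP_axis", "rS", "dI_stim", "dI_som",
                    "g_threshold", "lambda_threshold"},
    "sweep": {"weights", "values", "fixed_rates", "dI_stim"},
    "noisy": {"rates", "dI_som", "dI_stim", "stim_amplitude", "tau_xi",
              "sigma", "dt", "T", "burn_in", "mode"},
    "tuning": {"dI_som", "Iback", "theta_axis", "wff", "theta_p",
               "sigma_theta"},
}


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    circuit: dict
    experiment: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    provenance: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(
                f"unknown experiment {self.experiment!r}; expected one of {EXPERIMENTS}"
            )
        unknown = set(self.circuit) - _CIRCUIT_KEYS
        if unknown:
            raise ConfigError(f"unknown circuit keys: {sorted(unknown)}")
        unknown = set(self.params) - _PARAM_KEYS[self.experiment]
        if unknown:
            raise ConfigError(
                f"unknown {self.experiment!r} parameter keys: {sorted(unknown)}"
            )
        self.seed = int(self.seed)

    def circuit_params(self) -> CircuitParams:
        return CircuitParams.from_weights(**self.circuit)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "circuit": dict(self.circuit),
            "experiment": self.experiment,
            "params": _plain(self.params),
            "seed": self.seed,
            "provenance": dict(self.provenance),
        }

    def save(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=False))
        else:
            path.write_text(json.dumps(data, indent=2))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        unknown = set(data) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        missing = {"circuit", "experiment"} - set(data)
        if missing:
            raise ConfigError(f"missing required keys: {sorted(missing)}")
        return cls(
            circuit=dict(data["circuit"]),
            experiment=data["experiment"],
            params=dict(data.get("params", {})),
            seed=data.get("seed", 0),
            provenance=dict(data.get("provenance", {})),
            name=data.get("name", ""),
        )


def _plain(obj):
    """Recursively convert numpy scalars/arrays to JSON-serializable types."""
    import numpy as np

    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
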