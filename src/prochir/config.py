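"""Run configuration: strict YAML schema, seeds, logging helpers."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "ConfigError", "setup_logging"]

logger = logging.getLogger("prochir")

#: allowed keys per block; None means any scalar
_SCHEMA = {
    "preset": None,
    "output_dir": None,
    "log_level": None,
    "seeds": {"sampling": None, "selection": None, "dynamics": None,
              "fixtures": None},
    "pes": {"dE_vert": None, "barrier_S0": None, "barrier_S1": None,
            "tau_ci": None, "tau0": None, "phi0": None,
            "coupling_width": None, "coupling_strength": None,
            "I_tau": None, "I_phi": None, "nacv_cap": None,
            "preset_name": None},
    "sampling": {"n": None, "k": None},
    "dynamics": {"dt": None, "n_steps": None, "initial_state": None,
                 "frustrated": None, "decoherence": None,
                 "energy_drift_tol": None, "stop_tau": None,
                 "substep_gap": None, "substeps": None},
    "spectra": {"width": None, "convention": None, "blue_shift_ev": None,
                "strength_type": None},
    "kinetics": {"k_ct": None, "k_cD": None, "k_Dc": None, "k_tc": None,
                 "k_rac": None, "convention": None, "regime": None,
                 "window": None},
}


class ConfigError(ValueError):
    """Unknown key or missing seed in a run configuration."""


@dataclass
class RunConfig:
    """Validated run configuration with mandatory seeds."""

    preset: str = "stilbene"
    output_dir: str = "prochir_out"
    log_level: str = "INFO"
    seeds: dict = field(default_factory=dict)
    pes: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("sampling", "selection", "dynamics", "fixtures"):
            self.seeds.setdefault(name, 0)
        for name, val in self.seeds.items():
            if not isinstance(val, int):
                raise ConfigError(f"seed {name!r} must be an integer")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "preset": self.preset,
                "seeds": self.seeds,
                "pes": self.pes,
                "sampling": self.sampling,
                "dynamics": self.dynamics,
                "spectra": self.spectra,
                "kinetics": self.kinetics,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _check_keys(data: dict, schema: dict, path: str = "") -> None:
    for key, val in data.items():
        if key not in schema:
            raise ConfigError(f"unknown config key {path + key!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config block {path + key!r} must be a mapping")
            _check_keys(val, sub, path + key + ".")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(raw, _SCHEMA)
    return RunConfig(**raw)


def setup_logging(level: str = "INFO", logfile=None) -> None:
    handlers = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
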