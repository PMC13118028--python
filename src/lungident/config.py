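"""Configuration files, run manifests and result export.

A single YAML file with sections ``model``, ``grid``, ``excitation``,
``noise``, ``pathology``, ``fit``, ``cohort`` and ``classify`` drives every
pipeline stage.  :func:`default_config` returns the package defaults — the
reference study conditions — and any subset of keys may be overridden in a
user file; missing sections fall back to the defaults.

Every CLI run writes a ``RunManifest`` JSON next to its outputs: the full
resolved config, the seeds used, the package version, timestamps, and a
checksum inventory of the files produced, which together suffice to re-run
the deterministic stages bit-identically.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import CohortConfig
from .frf import ExcitationSpec, FrequencyGrid
from .inverse import FitSpec
from .model import PathologySpec, ThoraxModel, default_model
from .noise import NoiseSpec

__all__ = [
    "ConfigError",
    "default_config",
    "load_config",
    "save_config",
    "build_model",
    "build_grid",
    "build_excitation",
    "build_noise",
    "build_pathologies",
    "build_fit_spec",
    "build_cohort_config",
    "RunManifest",
]


class ConfigError(ValueError):
    """Configuration failed validation; the message names the offending field."""


def default_config() -> dict:
    """The package's reference configuration as a plain nested dict."""
    from .model import (
        DAMPING_BETA,
        DEFAULT_MASSES,
        DEFAULT_STIFFNESS,
        DEFAULT_SUPPORT_DAMPING,
    )

    return {
        "model": {
            "masses": list(DEFAULT_MASSES),
            "springs": dict(DEFAULT_STIFFNESS),
            "damping_beta": DAMPING_BETA,
            "support_damping": DEFAULT_SUPPORT_DAMPING,
        },
        "grid": {"f_min": 5.0, "f_max": 150.0, "n_points": 300},
        "excitation": {"amplitude": 1.0, "driven_dof": 0},
        "noise": {
            "relative_sigma": 0.02,
            "seed": 0,
            "floor": 1.0e-12,
            "mode": "relative",
        },
        "pathology": {
            "healthy": {"stiffness_factors": {}},
            "fibrosis_RU": {"stiffness_factors": {"k01": 1.5}},
            "fibrosis_RL": {"stiffness_factors": {"k02": 1.5}},
        },
        "fit": {
            "free_parameters": ["k01", "k02"],
            "truth": {"k01": 240.0, "k02": 154.0},
            "bounds_factor": [0.5, 2.0],
            "observed_dofs": [0],
            "max_iterations": 500,
            "regularization_weight": 0.0,
            "residual_scale": "linear",
            "n_starts": 5,
            "noise_seed": 0,
        },
        "cohort": {
            "conditions": ["healthy", "fibrosis_RU", "fibrosis_RL"],
            "per_class": 30,
            "jitter_sigma": 0.0,
            "seed": 0,
        },
        "classify": {
            "test_fraction": 0.30,
            "n_components": 6,
            "max_iterations": 1000,
            "split_seed": 0,
        },
        "sensitivity": {
            "parameters": ["k01", "k02"],
            "step_fraction": 0.01,
            "scheme": "forward",
            "mode": "relative",
        },
    }


def _deep_update(base: dict, override: dict, path: str = "") -> dict:
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            # open maps (springs, pathology entries, ...) merge new entries
            if key in ("pathology", "springs", "stiffness_factors", "truth"):
                base[key] = {**base[key], **copy.deepcopy(value)}
            else:
                _deep_update(base[key], value, here)
        else:
            base[key] = copy.deepcopy(value)
    return base


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, filling unspecified sections with defaults."""
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config root must be a mapping")
        _deep_update(config, user)
    validate_config(config)
    return config


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True, default_flow_style=False)


def validate_config(config: dict) -> None:
    """Build every domain object once, surfacing field-level errors."""
    try:
        model = build_model(config)
        build_grid(config)
        build_excitation(config)
        build_noise(config)
        build_pathologies(config)
        build_fit_spec(config)
        build_cohort_config(config)
        for p in config["fit"]["truth"]:
            model.spring(p)
    except ConfigError:
        raise
    except (ValueError, KeyError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


# -- builders ---------------------------------------------------------------

def build_model(config: dict) -> ThoraxModel:
    m = config["model"]
    return default_model(
        stiffness=m["springs"],
        masses=m["masses"],
        damping_beta=m["damping_beta"],
        support_damping=m["support_damping"],
    )


def build_grid(config: dict) -> FrequencyGrid:
    g = config["grid"]
    return FrequencyGrid(np.linspace(g["f_min"], g["f_max"], g["n_points"]))


def build_excitation(config: dict) -> ExcitationSpec:
    e = config["excitation"]
    return ExcitationSpec(amplitude=e["amplitude"], driven_dof=e["driven_dof"])


def build_noise(config: dict, seed: int | None = None) -> NoiseSpec:
    n = config["noise"]
    return NoiseSpec(
        relative_sigma=n["relative_sigma"],
        seed=n["seed"] if seed is None else seed,
        floor=n["floor"],
        mode=n["mode"],
    )


def build_pathologies(config: dict) -> dict[str, PathologySpec]:
    out = {}
    for name, entry in config["pathology"].items():
        condition = name if name in (
            "healthy",
            "fibrosis_RU",
            "fibrosis_RL",
            "emphysema",
            "focal",
        ) else "focal"
        out[name] = PathologySpec(
            condition=condition,
            stiffness_factors=entry.get("stiffness_factors", {}),
            mass_factors={
                int(k): v for k, v in entry.get("mass_factors", {}).items()
            },
        )
    return out


def build_fit_spec(config: dict) -> FitSpec:
    f = config["fit"]
    return FitSpec(
        free_parameters=tuple(f["free_parameters"]),
        bounds_factor=tuple(f["bounds_factor"]),
        observed_dofs=tuple(f["observed_dofs"]),
        max_iterations=f["max_iterations"],
        regularization_weight=f["regularization_weight"],
        residual_scale=f["residual_scale"],
        n_starts=f["n_starts"],
    )


def build_cohort_config(config: dict, seed: int | None = None) -> CohortConfig:
    c = config["cohort"]
    return CohortConfig(
        conditions=tuple(c["conditions"]),
        per_class=c["per_class"],
        grid=build_grid(config),
        noise=build_noise(config),
        jitter_sigma=c["jitter_sigma"],
        seed=c["seed"] if seed is None else seed,
        pathologies=build_pathologies(config),
    )


# -- run manifest -----------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run, written as JSON next to the outputs."""

    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    version: str = __version__
    started: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    finished: str | None = None
    outputs: dict = field(default_factory=dict)

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = {"path": str(path), "sha256": _sha256(path)}

    def write(self, path: str | Path) -> None:
        self.finished = datetime.now(timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(
                {
                    "command": self.command,
                    "version": self.version,
                    "started": self.started,
                    "finished": self.finished,
                    "seeds": self.seeds,
                    "config": self.config,
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                default=str,
            )
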