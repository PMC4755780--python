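"""Run configuration: YAML schema, defaults, and validation.

A run config is a YAML mapping with blocks ``dynamics``, ``environment``,
``evolution``, ``analysis`` plus global ``seed``, ``output_dir`` and
``schema_version``.  Every key has a default (the reference parameter set of
the model); unknown keys are rejected and all validation failures are
reported together.  The fully resolved config (defaults filled in) is what
gets written alongside run outputs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .dynamics import SocialParams
from .environment import ResourceField, make_field
from .evolution import EvolutionConfig
from .geometry import TorusGeometry

__all__ = ["ConfigError", "RunConfig", "EnvironmentConfig", "AnalysisConfig",
           "load_config", "resolve", "DEFAULTS"]

SCHEMA_VERSION = 1

DEFAULTS: dict[str, Any] = {
    "schema_version": SCHEMA_VERSION,
    "seed": 0,
    "output_dir": "runs",
    "dynamics": {
        "Cr": 1.1, "Ca": 1.0, "lr": 1.0, "la": 7.5, "k": 25,
        "m": 1.0, "eta": 1.0, "gamma": 0.01, "tau": 1.0, "n_sub": 10,
    },
    "environment": {
        "M": 2, "lam0": 10.0, "lam1": 20.0, "alpha": [1.0, 0.0], "beta": 0.1,
        "tau_p": 1500.0, "u": 0.0, "edge_length": 346.0,
        "centroids": "uniform",  # or an explicit [[x, y], ...] list
        "rho": 0.16,  # recorded as metadata only
    },
    "evolution": {
        "N": 500, "generations": 100, "T_gen": 1500,
        "sigma_psi0": 0.05, "sigma_psi1": 0.05, "sigma_lmax": 0.5,
        "lmax_cap": 30.0, "asocial_mode": False, "lmax_asocial": 2.0,
        "reset_environment": False,
    },
    "analysis": {
        "psi_lower": 0.0, "psi_upper": 2.95, "n_neighbors": 10,
        "kl_bins": 30, "kl_rmax_factor": 3.0, "eps_bin": 1e-9,
    },
}


class ConfigError(ValueError):
    """Raised with a message listing every failing key."""


@dataclass(frozen=True)
class EnvironmentConfig:
    n_peaks: int = 2
    amplitude: float = 10.0
    decay_length: float = 20.0
    drift: tuple[float, float] = (1.0, 0.0)
    diffusion_sd: float = 0.1
    relocation_timescale: float = 1500.0
    depletion_rate: float = 0.0
    edge_length: float = 346.0
    centroids: Any = "uniform"
    rho: float = 0.16  # undefined in the source parameter list; metadata only

    @property
    def geometry(self) -> TorusGeometry:
        return TorusGeometry(self.edge_length)

    def build_field(self, rng: np.random.Generator) -> ResourceField:
        centroids = None if self.centroids == "uniform" else np.asarray(self.centroids, dtype=float)
        return make_field(
            rng, n_peaks=self.n_peaks, amplitude=self.amplitude,
            decay_length=self.decay_length, geometry=self.geometry,
            drift=self.drift, diffusion_sd=self.diffusion_sd,
            relocation_timescale=self.relocation_timescale,
            depletion_rate=self.depletion_rate, centroids=centroids,
        )


@dataclass(frozen=True)
class AnalysisConfig:
    psi_lower: float = 0.0
    psi_upper: float = 2.95
    n_neighbors: int = 10
    kl_bins: int = 30
    kl_rmax_factor: float = 3.0
    eps_bin: float = 1e-9


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    schema_version: int
    dynamics: SocialParams
    environment: EnvironmentConfig
    evolution: EvolutionConfig
    analysis: AnalysisConfig
    resolved: dict[str, Any]  # full dict with all defaults filled in


def _merge(user: dict[str, Any]) -> tuple[dict[str, Any], list[str]]:
    resolved = copy.deepcopy(DEFAULTS)
    errors: list[str] = []
    for key, value in user.items():
        if key not in DEFAULTS:
            errors.append(f"{key}: unknown key")
            continue
        if isinstance(DEFAULTS[key], dict):
            if not isinstance(value, dict):
                errors.append(f"{key}: expected a mapping")
                continue
            for sub, sval in value.items():
                if sub not in DEFAULTS[key]:
                    errors.append(f"{key}.{sub}: unknown key")
                else:
                    resolved[key][sub] = sval
        else:
            resolved[key] = value
    return resolved, errors


def resolve(user: dict[str, Any] | None) -> RunConfig:
    """Validate a (possibly partial) config dict and fill in all defaults."""
    resolved, errors = _merge(user or {})

    def build(label, fn):
        try:
            return fn()
        except (ValueError, TypeError) as exc:
            errors.append(f"{label}: {exc}")
            return None

    d = resolved["dynamics"]
    dynamics = build("dynamics", lambda: SocialParams(
        repulsion_strength=float(d["Cr"]), attraction_strength=float(d["Ca"]),
        repulsion_length=float(d["lr"]), attraction_length=float(d["la"]),
        neighbor_count=int(d["k"]), mass=float(d["m"]), damping=float(d["eta"]),
        noise_magnitude=float(d["gamma"]), time_step=float(d["tau"]),
        n_sub=int(d["n_sub"]),
    ))
    e = resolved["environment"]
    environment = build("environment", lambda: EnvironmentConfig(
        n_peaks=int(e["M"]), amplitude=float(e["lam0"]), decay_length=float(e["lam1"]),
        drift=tuple(float(v) for v in e["alpha"]), diffusion_sd=float(e["beta"]),
        relocation_timescale=float(e["tau_p"]), depletion_rate=float(e["u"]),
        edge_length=float(e["edge_length"]), centroids=e["centroids"], rho=float(e["rho"]),
    ))
    if environment is not None and environment.edge_length <= 0:
        errors.append("environment.edge_length: must be > 0")
    v = resolved["evolution"]
    evolution = build("evolution", lambda: EvolutionConfig(
        population_size=int(v["N"]), generations=int(v["generations"]),
        steps_per_generation=int(v["T_gen"]), sigma_psi0=float(v["sigma_psi0"]),
        sigma_psi1=float(v["sigma_psi1"]), sigma_lmax=float(v["sigma_lmax"]),
        lmax_bounds=(0.0, float(v["lmax_cap"])), asocial_mode=bool(v["asocial_mode"]),
        lmax_asocial=float(v["lmax_asocial"]), reset_environment=bool(v["reset_environment"]),
    ))
    a = resolved["analysis"]
    analysis = build("analysis", lambda: AnalysisConfig(
        psi_lower=float(a["psi_lower"]), psi_upper=float(a["psi_upper"]),
        n_neighbors=int(a["n_neighbors"]), kl_bins=int(a["kl_bins"]),
        kl_rmax_factor=float(a["kl_rmax_factor"]), eps_bin=float(a["eps_bin"]),
    ))
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(sorted(errors)))
    return RunConfig(
        seed=int(resolved["seed"]), output_dir=str(resolved["output_dir"]),
        schema_version=int(resolved["schema_version"]),
        dynamics=dynamics, environment=environment, evolution=evolution,
        analysis=analysis, resolved=resolved,
    )


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; ``None`` yields all defaults."""
    if path is None:
        return resolve({})
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    user = yaml.safe_load(p.read_text())
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError("config root must be a mapping")
    return resolve(user)
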