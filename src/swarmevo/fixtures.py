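"""Deterministic scenario catalog and synthetic data generators.

Every scenario is fully self-describing (state, traits, parameters, field,
seed) and carries an executable expected-properties manifest; the test suite
replays every catalog entry.  ``synth_counts`` generates arrival-count time
series from the linear / exponential models used by the arrival-curve fits,
for fit-recovery round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field, replace
from typing import Any

import numpy as np

from .analysis import kl_divergence_to_resource
from .dynamics import AgentState, SocialParams, Traits, force_balance_distance
from .environment import ResourceField, make_field
from .geometry import TorusGeometry
from .simulate import SimulationResult, simulate

__all__ = ["Scenario", "SCENARIO_NAMES", "make_scenario", "run_scenario", "verify", "synth_counts"]

ESST_TRAITS = (3.0, 2.45, 29.0)  # population means at the evolutionarily stable state


@dataclass
class Scenario:
    """A seeded, replayable toy configuration with assertion manifest.

    ``expected`` maps check names to (metric, op, value) triples evaluated by
    :func:`verify` on the scenario's own simulation output.
    """

    name: str
    seed: int
    n_steps: int
    params: SocialParams
    traits: Traits
    state: AgentState
    field: ResourceField | None
    geometry: TorusGeometry
    expected: dict[str, tuple[str, str, float]] = dataclass_field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _pair_scenario(seed: int) -> Scenario:
    params = SocialParams(noise_magnitude=0.0)
    d_star = force_balance_distance(params)
    geometry = TorusGeometry(50.0)
    pos = np.array([[20.0, 25.0], [20.0 + d_star, 25.0]])
    vel = np.zeros((2, 2))
    return Scenario(
        name="two_agent_balance", seed=seed, n_steps=200, params=params,
        traits=Traits.uniform(2, 0.0, 0.0, 30.0),
        state=AgentState(pos, vel), field=None, geometry=geometry,
        expected={"separation_stays_at_balance": ("pair_separation", "approx", d_star)},
    )


def _peak_scenario(seed: int, name: str, psi0: float, psi1: float, lmax: float,
                   n: int = 200, moving: bool = False) -> Scenario:
    params = SocialParams()
    rng = np.random.default_rng(seed)
    geometry = TorusGeometry(218.8)  # preserves the reference number density at n=200
    drift = (0.06, 0.0) if moving else (0.0, 0.0)
    beta = 0.5 if moving else 0.0
    field = make_field(
        rng, n_peaks=1, amplitude=10.0, decay_length=12.65, geometry=geometry,
        drift=drift, diffusion_sd=beta, relocation_timescale=1e12,
        centroids=np.array([[geometry.edge_length / 2, geometry.edge_length / 2]]),
    )
    state = AgentState.random(rng, n, geometry)
    expected: dict[str, tuple[str, str, float]] = {"agents_keep_moving": ("mean_speed", ">", 0.0)}
    if name == "esst_static_peak":
        expected["density_converges_to_resource"] = ("kl_decrease", ">", 0.0)
    return Scenario(
        name=name, seed=seed, n_steps=1500, params=params,
        traits=Traits.uniform(n, psi0, psi1, lmax),
        state=state, field=field, geometry=geometry, expected=expected,
    )


_CATALOG = {
    "two_agent_balance": _pair_scenario,
    "esst_static_peak": lambda seed: _peak_scenario(seed, "esst_static_peak", *ESST_TRAITS),
    "asocial_static_peak": lambda seed: _peak_scenario(
        seed, "asocial_static_peak", ESST_TRAITS[0], ESST_TRAITS[1], 2.0),
    "perturbed_low_psi0": lambda seed: _peak_scenario(
        seed, "perturbed_low_psi0", 0.4, ESST_TRAITS[1], ESST_TRAITS[2], moving=True),
    "perturbed_high_psi0": lambda seed: _peak_scenario(
        seed, "perturbed_high_psi0", 8.8, ESST_TRAITS[1], ESST_TRAITS[2], moving=True),
}

SCENARIO_NAMES = tuple(_CATALOG)


def make_scenario(name: str, seed: int = 0, **overrides: Any) -> Scenario:
    """Build a catalog scenario, optionally overriding any Scenario field."""
    if name not in _CATALOG:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    sc = _CATALOG[name](seed)
    if overrides:
        bad = set(overrides) - set(sc.__dataclass_fields__)
        if bad:
            raise ValueError(f"invalid scenario overrides: {sorted(bad)}")
        sc = replace(sc, **overrides)
    return sc


def run_scenario(sc: Scenario, n_steps: int | None = None,
                 record_every: int = 0) -> SimulationResult:
    """Replay a scenario from its seed (bit-reproducible when gamma = 0)."""
    return simulate(
        sc.state.copy(), sc.traits, sc.params, sc.field, n_steps or sc.n_steps,
        sc.rng(), geometry=sc.geometry, record_every=record_every,
        advance_field=sc.field is not None,
    )


def _metric(sc: Scenario, name: str) -> float:
    kl0 = None
    if name == "kl_decrease":
        kl0 = kl_divergence_to_resource(sc.state, sc.field)
    res = run_scenario(sc)
    if name == "pair_separation":
        return float(sc.geometry.distance(res.state.positions[0], res.state.positions[1]))
    if name == "mean_speed":
        return float(res.state.speeds.mean())
    if name == "kl_decrease":
        return kl0 - kl_divergence_to_resource(res.state, sc.field)
    raise KeyError(f"unknown scenario metric {name!r}")


def verify(sc: Scenario, rtol: float = 1e-6) -> dict[str, tuple[bool, float]]:
    """Evaluate the scenario's expected-properties manifest.

    Returns check name -> (passed, measured value)."""
    out = {}
    for check, (metric, op, value) in sc.expected.items():
        measured = _metric(sc, metric)
        if op == "approx":
            ok = abs(measured - value) <= rtol * max(1.0, abs(value))
        elif op == ">":
            ok = measured > value
        elif op == "<":
            ok = measured < value
        else:
            raise ValueError(f"unknown manifest op {op!r}")
        out[check] = (ok, measured)
    return out


def synth_counts(
    model: str,
    parameters: dict[str, float],
    noise_sd: float,
    n_steps: int,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic arrival-count series from the linear or exponential model.

    ``linear``: c + kappa_a * t;  ``exponential``: kappa_s1 + exp(kappa_s2 * t).
    With ``noise_sd > 0``, i.i.d. Gaussian noise is added and the series is
    floored at zero and rounded to integer counts; noise-free series are
    returned exact so they can serve as fit-recovery oracles.
    """
    if n_steps < 2:
        raise ValueError("need n_steps >= 2")
    t = np.arange(n_steps, dtype=float)
    if model == "linear":
        y = parameters.get("intercept", 0.0) + parameters["kappa_a"] * t
    elif model == "exponential":
        y = parameters["kappa_s1"] + np.exp(parameters["kappa_s2"] * t)
    else:
        raise ValueError("model must be 'linear' or 'exponential'")
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noisy series require an rng")
        y = np.round(np.maximum(y + rng.normal(0.0, noise_sd, n_steps), 0.0))
    return t, y
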