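"""Canonical study protocols at desk scale.

The reference system is N = 500 agents on a torus of edge 346 lr with two
Gaussian resource peaks (lam0 = 10, lam1 = 20).  Desk-scale runs use N = 200
with two scaling rules chosen to preserve the structure of the full-scale
system rather than its raw sizes:

* **Density preservation** — the domain edge scales as ``346 * sqrt(N/500)``,
  keeping the number density (and hence the locations of the collective-state
  transitions, which are nucleation phenomena) unchanged.
* **Capacity preservation** — the peak decay length scales the same way,
  ``20 * sqrt(N/500)``, keeping the number of agents a peak can hold at the
  crystal spacing set by the pair force (proportional to lam1**2)
  proportional to N.  Without this, scaled populations can never saturate a
  peak and the competitive structure of the fitness landscape is lost.

Dynamic-peak runs use the drift/diffusion values under which collective
tracking is demonstrable, alpha = (0.06, 0) and beta = 0.5 per step, with
relocation timescale tau_p = 1500.

The station-keeping contour of a phenotype (psi0, psi1) on a peak of height
lam0 sits at radius ``r* = lam1 * sqrt(ln(lam0 psi1 / psi0))``; arrivals
accumulate there, so arrival counts in these protocols use r* rather than
one decay length (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import stats

from .analysis import (
    ArrivalCurve,
    SweepResult,
    fit_arrival,
    group_peak_matching,
    hysteresis_sweep,
    kl_divergence_to_resource,
    transition_edges,
)
from .dynamics import AgentState, SocialParams, Traits
from .environment import ResourceField, make_field
from .evolution import EvolutionConfig, GenerationRecord, run_evolution
from .fixtures import ESST_TRAITS
from .geometry import TorusGeometry
from .seeding import stream
from .simulate import simulate

__all__ = [
    "REFERENCE_N",
    "scaled_edge_length",
    "scaled_decay_length",
    "station_keeping_radius",
    "dynamic_peaks_field",
    "hysteresis_protocol",
    "EvolutionRun",
    "evolution_protocol",
    "paired_evolution_protocol",
    "TrackingResult",
    "tracking_protocol",
    "peak_matching_protocol",
]

REFERENCE_N = 500
REFERENCE_EDGE = 346.0
REFERENCE_DECAY = 20.0
PEAK_AMPLITUDE = 10.0
TRACKABLE_DRIFT = (0.06, 0.0)
TRACKABLE_DIFFUSION = 0.5
RELOCATION_TIMESCALE = 1500.0


def scaled_edge_length(n_agents: int) -> float:
    """Domain edge preserving the reference number density."""
    return REFERENCE_EDGE * np.sqrt(n_agents / REFERENCE_N)


def scaled_decay_length(n_agents: int) -> float:
    """Peak decay length preserving peak carrying capacity relative to N."""
    return REFERENCE_DECAY * np.sqrt(n_agents / REFERENCE_N)


def station_keeping_radius(psi0: float, psi1: float, lam0: float, lam1: float) -> float:
    """Radius of the Psi = 0 contour on a single peak (where arrivals park)."""
    s_star = psi0 / psi1
    if s_star >= lam0:
        return 0.0
    return float(lam1 * np.sqrt(np.log(lam0 / s_star)))


def dynamic_peaks_field(
    rng: np.random.Generator,
    n_agents: int = 200,
    n_peaks: int = 2,
    geometry: TorusGeometry | None = None,
) -> ResourceField:
    """The dynamic two-peak landscape used by the evolution protocols."""
    geometry = geometry or TorusGeometry(scaled_edge_length(n_agents))
    return make_field(
        rng, n_peaks=n_peaks, amplitude=PEAK_AMPLITUDE,
        decay_length=scaled_decay_length(n_agents), geometry=geometry,
        drift=TRACKABLE_DRIFT, diffusion_sd=TRACKABLE_DIFFUSION,
        relocation_timescale=RELOCATION_TIMESCALE,
    )


# ---------------------------------------------------------------------------
# hysteresis (uniform environment)
# ---------------------------------------------------------------------------

def hysteresis_protocol(
    seed: int,
    n_agents: int = 200,
    equilibration_steps: int = 2000,
    replicates: int = 10,
    psi_step: float = 0.2,
) -> tuple[SweepResult, SweepResult, tuple[float, float]]:
    """Full hysteresis sweep (Psi 4 -> -1 -> 4) at desk scale.

    Returns (decreasing branch, increasing branch, (lower, upper) edges of
    the transitional regime)."""
    rng = stream(seed, "hysteresis")
    geometry = TorusGeometry(scaled_edge_length(n_agents))
    down, up = hysteresis_sweep(
        SocialParams(), n_agents, rng, psi_step=psi_step,
        equilibration_steps=equilibration_steps, replicates=replicates,
        geometry=geometry,
    )
    return down, up, transition_edges(down, up)


# ---------------------------------------------------------------------------
# paired evolution (dynamic peaks)
# ---------------------------------------------------------------------------

@dataclass
class EvolutionRun:
    seed: int
    asocial: bool
    records: list[GenerationRecord]

    def post_burnin(self, burnin: int = 150) -> list[GenerationRecord]:
        return self.records[burnin:]

    def mean_fitness(self, burnin: int = 150) -> float:
        return float(np.mean([r.mean_fitness for r in self.post_burnin(burnin)]))

    def mean_cv(self, burnin: int = 150) -> float:
        return float(np.nanmean([r.fitness_cv for r in self.post_burnin(burnin)]))

    def final_trait_means(self) -> dict[str, float]:
        return self.records[-1].trait_means


def evolution_protocol(
    seed: int,
    asocial: bool = False,
    n_agents: int = 200,
    generations: int = 300,
    steps_per_generation: int = 500,
) -> EvolutionRun:
    """One scaled evolution run in the dynamic two-peak landscape."""
    label = "evolve-asocial" if asocial else "evolve-social"
    rng = stream(seed, label)
    config = EvolutionConfig(
        population_size=n_agents, generations=generations,
        steps_per_generation=steps_per_generation, asocial_mode=asocial,
    )
    field = dynamic_peaks_field(rng, n_agents)
    records = run_evolution(config, SocialParams(), field, rng)
    return EvolutionRun(seed=seed, asocial=asocial, records=records)


def paired_evolution_protocol(
    seed: int, n_seeds: int = 3, **kwargs
) -> tuple[list[EvolutionRun], list[EvolutionRun]]:
    """Paired social and asocial runs over ``n_seeds`` derived seeds."""
    social = [evolution_protocol(seed + i, asocial=False, **kwargs) for i in range(n_seeds)]
    asocial = [evolution_protocol(seed + i, asocial=True, **kwargs) for i in range(n_seeds)]
    return social, asocial


# ---------------------------------------------------------------------------
# collective computation on a static peak
# ---------------------------------------------------------------------------

@dataclass
class TrackingResult:
    """KL trend and arrival fit for one seeded static-peak run."""

    seed: int
    kl_times: np.ndarray
    kl_values: np.ndarray
    kl_spearman: float
    arrival: ArrivalCurve
    final_count: int


def tracking_protocol(
    seed: int,
    social: bool = True,
    n_agents: int = 200,
    n_steps: int = 1500,
    kl_every: int = 50,
) -> TrackingResult:
    """ESSt-trait population (or its asocial control, lmax = 2) accumulating
    on a static capacity-scaled peak from uniform initial conditions."""
    rng = stream(seed, "track-social" if social else "track-asocial")
    geometry = TorusGeometry(scaled_edge_length(n_agents))
    lam1 = scaled_decay_length(n_agents)
    center = np.full(2, geometry.edge_length / 2)
    field = make_field(
        rng, n_peaks=1, amplitude=PEAK_AMPLITUDE, decay_length=lam1,
        geometry=geometry, drift=(0.0, 0.0), diffusion_sd=0.0,
        relocation_timescale=1e12, centroids=center.reshape(1, 2),
    )
    psi0, psi1, lmax_esst = ESST_TRAITS
    traits = Traits.uniform(n_agents, psi0, psi1, lmax_esst if social else 2.0)
    state = AgentState.random(rng, n_agents, geometry)
    radius = station_keeping_radius(psi0, psi1, PEAK_AMPLITUDE, lam1)
    res = simulate(state, traits, SocialParams(), field, n_steps, rng,
                   record_every=kl_every, track_peak=0, track_radius=radius,
                   advance_field=False)
    kl = np.array([kl_divergence_to_resource(s, field) for s in res.snapshots])
    rho = float(stats.spearmanr(res.snapshot_times, kl).statistic)
    curve = fit_arrival(np.arange(n_steps, dtype=float), res.peak_counts)
    return TrackingResult(
        seed=seed, kl_times=np.asarray(res.snapshot_times, dtype=float),
        kl_values=kl, kl_spearman=rho, arrival=curve,
        final_count=int(res.peak_counts[-1]),
    )


# ---------------------------------------------------------------------------
# group size vs peak mass
# ---------------------------------------------------------------------------

def peak_matching_protocol(
    seed: int,
    mass_ratio: float = 2.0,
    replicates: int = 20,
    n_agents: int = 200,
    n_steps: int = 1500,
    window: int = 500,
) -> pd.DataFrame:
    """Two static peaks with total amplitude 2*lam0 split ``mass_ratio``:1;
    mean size of the group nearest each peak over the final ``window`` steps,
    averaged over replicates.  Returns one row per (replicate, peak)."""
    geometry = TorusGeometry(scaled_edge_length(n_agents))
    lam1 = scaled_decay_length(n_agents)
    L = geometry.edge_length
    amps = np.array([mass_ratio, 1.0]) / (mass_ratio + 1.0) * (2 * PEAK_AMPLITUDE)
    rows = []
    for rep in range(replicates):
        rng = stream(seed, "match-peaks", rep)
        field = make_field(
            rng, n_peaks=2, amplitude=1.0, decay_length=lam1, geometry=geometry,
            drift=(0.0, 0.0), diffusion_sd=0.0, relocation_timescale=1e12,
            centroids=np.array([[L / 4, L / 2], [3 * L / 4, L / 2]]),
        )
        for p, a in zip(field.peaks, amps):
            p.amplitude = float(a)
            p.initial_amplitude = float(a)
        traits = Traits.uniform(n_agents, *ESST_TRAITS)
        state = AgentState.random(rng, n_agents, geometry)
        stride = 50
        res = simulate(state, traits, SocialParams(), field, n_steps, rng,
                       record_every=stride, advance_field=False)
        keep = [s for t, s in zip(res.snapshot_times, res.snapshots)
                if t > n_steps - window]
        table = group_peak_matching(keep, traits, SocialParams(), field)
        for _, row in table.iterrows():
            rows.append({"replicate": rep, "peak": int(row["peak"]),
                         "peak_mass": row["peak_mass"],
                         "mean_group_size": row["mean_group_size"]})
    return pd.DataFrame(rows)
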