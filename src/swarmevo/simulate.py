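"""Multi-step simulation driver tying agents to the dynamic resource field.

One loop iteration = one time step tau: agents move synchronously from
start-of-step information (:func:`swarmevo.dynamics.step`), then the resource
is optionally depleted at the agents' start-of-step positions, then the peaks
move/relocate.  Per-agent resource values are accumulated every step so the
driver can report lifetime mean experienced resource (the fitness currency).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .dynamics import AgentState, SocialParams, Traits, step
from .environment import ResourceField
from .geometry import TorusGeometry

__all__ = ["SimulationResult", "simulate"]


@dataclass
class SimulationResult:
    """Outcome of a fixed number of time steps."""

    state: AgentState  # final agent state
    mean_s: np.ndarray  # per-agent mean resource experienced (pre-depletion)
    n_steps: int
    snapshot_times: list[int] = dataclass_field(default_factory=list)
    snapshots: list[AgentState] = dataclass_field(default_factory=list)
    peak_counts: np.ndarray | None = None  # per-step count near tracked peak
    consumed: np.ndarray | None = None  # per-agent total consumption (depletion)


def simulate(
    state: AgentState,
    traits: Traits,
    params: SocialParams,
    field: ResourceField | None,
    n_steps: int,
    rng: np.random.Generator,
    geometry: TorusGeometry | None = None,
    record_every: int = 0,
    track_peak: int | None = None,
    track_radius: float | None = None,
    advance_field: bool = True,
) -> SimulationResult:
    """Run ``n_steps`` time steps and return the final state plus summaries.

    Parameters
    ----------
    record_every
        If > 0, store a full state snapshot every that many steps (plus the
        initial state at t=0).
    track_peak
        If given, count agents within ``track_radius`` (default: that peak's
        decay length) of the peak's centre at every step.
    advance_field
        Set False to hold the resource field static (peaks neither move nor
        relocate); depletion still applies if configured.
    """
    geometry = geometry or (field.geometry if field is not None else TorusGeometry())
    n = state.n
    s_sum = np.zeros(n)
    consumed = np.zeros(n) if (field is not None and field.depletion_rate > 0) else None
    counts = np.empty(n_steps, dtype=np.int64) if track_peak is not None else None
    if track_peak is not None and track_radius is None:
        track_radius = field.peaks[track_peak].decay_length

    snapshots: list[AgentState] = []
    snapshot_times: list[int] = []
    if record_every > 0:
        snapshots.append(state.copy())
        snapshot_times.append(0)

    cur = state
    for t in range(n_steps):
        if counts is not None:
            d = geometry.distance(cur.positions, field.peaks[track_peak].centroid)
            counts[t] = int(np.count_nonzero(d <= track_radius))
        prev_positions = cur.positions
        cur, s = step(cur, traits, params, field, rng, geometry)
        s_sum += s
        if field is not None:
            if field.depletion_rate > 0:
                consumed += field.deplete(prev_positions)
            if advance_field:
                field.step(rng)
        if record_every > 0 and (t + 1) % record_every == 0:
            snapshots.append(cur.copy())
            snapshot_times.append(t + 1)

    return SimulationResult(
        state=cur,
        mean_s=s_sum / max(n_steps, 1),
        n_steps=n_steps,
        snapshot_times=snapshot_times,
        snapshots=snapshots,
        peak_counts=counts,
        consumed=consumed,
    )
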