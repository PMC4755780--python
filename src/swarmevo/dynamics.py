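"""Per-step agent motion: social forces, resource-dependent self-propulsion,
and discretized integration on the torus.

Each agent i feels two forces.  The *social force* is the negative gradient of
a double-exponential pair potential summed over its k nearest neighbours
within its interaction range ``lmax``:

    F_s,i = sum_{j in N_i} [ (Cr/lr) e^{-d_ij/lr} - (Ca/la) e^{-d_ij/la} ] rhat_ij,

with short-range repulsion (Cr, lr) and longer-range attraction (Ca, la); the
parameter regime requires ``lr < la`` and ``Cr/lr > Ca/la`` so contact is
always repulsive.  The *autonomous force* accelerates the agent along its own
heading toward a resource-dependent preferred speed:

    F_a,i = [ Psi_i - eta |v_i|^2 ] v_i / |v_i|,   Psi_i = psi0_i - psi1_i S(x_i),

so agents slow down (Psi small or negative) where the resource S is high and
speed up where it is low.  One time step tau freezes F_s and S at their
start-of-step values, integrates velocity and position (semi-implicit Euler
with sub-stepping), then adds a navigational noise kick of exact magnitude
``gamma`` with uniform random heading.  All agents update synchronously.

The numpy implementations here are the reference (and test oracle); the
drivers use the identical numba kernels in :mod:`swarmevo._kernels`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np

from . import _kernels
from .environment import ResourceField
from .geometry import TorusGeometry

__all__ = [
    "LMAX_CAP",
    "SocialParams",
    "Traits",
    "AgentState",
    "neighbor_sets",
    "social_force",
    "response_speed_param",
    "autonomous_force",
    "step",
    "interaction_graph",
    "pair_force_coeff",
    "pair_potential",
    "force_balance_distance",
]

LMAX_CAP = 30.0  # maximum allowable interaction range


@dataclass(frozen=True)
class SocialParams:
    """Social-interaction and integration constants (lengths in lr, time in tau)."""

    repulsion_strength: float = 1.1  # Cr
    attraction_strength: float = 1.0  # Ca
    repulsion_length: float = 1.0  # lr
    attraction_length: float = 7.5  # la
    neighbor_count: int = 25  # k
    mass: float = 1.0  # m
    damping: float = 1.0  # eta
    noise_magnitude: float = 0.01  # gamma
    time_step: float = 1.0  # tau
    n_sub: int = 10  # sub-steps per tau (1 = plain Euler)

    def __post_init__(self) -> None:
        pos = {
            "repulsion_strength": self.repulsion_strength,
            "attraction_strength": self.attraction_strength,
            "repulsion_length": self.repulsion_length,
            "attraction_length": self.attraction_length,
            "mass": self.mass,
            "damping": self.damping,
            "time_step": self.time_step,
        }
        bad = [k for k, v in pos.items() if not v > 0]
        if bad:
            raise ValueError(f"parameters must be strictly positive: {bad}")
        if self.noise_magnitude < 0:
            raise ValueError("noise_magnitude must be >= 0")
        if self.neighbor_count < 0:
            raise ValueError("neighbor_count must be >= 0")
        if self.n_sub < 1:
            raise ValueError("n_sub must be >= 1")
        if not self.repulsion_length < self.attraction_length:
            raise ValueError("repulsion must be shorter-ranged than attraction (lr < la)")
        if not (self.repulsion_strength / self.repulsion_length
                > self.attraction_strength / self.attraction_length):
            raise ValueError("force at contact must be repulsive (Cr/lr > Ca/la)")

    @property
    def strength_ratio(self) -> float:
        """C = Cr/Ca."""
        return self.repulsion_strength / self.attraction_strength

    @property
    def length_ratio(self) -> float:
        """l = lr/la."""
        return self.repulsion_length / self.attraction_length


@dataclass
class Traits:
    """Per-agent heritable phenotype: (psi0, psi1, lmax)."""

    psi0: np.ndarray  # baseline speed parameter
    psi1: np.ndarray  # environmental sensitivity
    lmax: np.ndarray  # interaction range, in [0, cap]
    cap: float = LMAX_CAP  # maximum allowable interaction range

    def __post_init__(self) -> None:
        self.psi0 = np.atleast_1d(np.asarray(self.psi0, dtype=float))
        self.psi1 = np.atleast_1d(np.asarray(self.psi1, dtype=float))
        self.lmax = np.atleast_1d(np.asarray(self.lmax, dtype=float))
        if not (self.psi0.shape == self.psi1.shape == self.lmax.shape):
            raise ValueError("trait arrays must have identical shapes")
        if not np.all(np.isfinite(self.psi0)) or not np.all(np.isfinite(self.psi1)):
            raise ValueError("psi0 and psi1 must be finite")
        if np.any(self.lmax < 0) or np.any(self.lmax > self.cap):
            raise ValueError(f"lmax must lie in [0, {self.cap}]")

    @classmethod
    def uniform(cls, n: int, psi0: float, psi1: float, lmax: float, cap: float = LMAX_CAP) -> "Traits":
        return cls(np.full(n, psi0), np.full(n, psi1), np.full(n, lmax), cap)

    def copy(self) -> "Traits":
        return Traits(self.psi0.copy(), self.psi1.copy(), self.lmax.copy(), self.cap)

    def __len__(self) -> int:
        return self.psi0.size


@dataclass
class AgentState:
    """Positions (wrapped onto the torus) and velocities of N agents."""

    positions: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.velocities = np.asarray(self.velocities, dtype=float).reshape(-1, 2)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have matching shapes")
        if not np.all(np.isfinite(self.positions)) or not np.all(np.isfinite(self.velocities)):
            raise ValueError("state must be finite")

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        n: int,
        geometry: TorusGeometry,
        speed_range: tuple[float, float] = (0.0, 0.1),
    ) -> "AgentState":
        """Uniform random positions; small random speeds with uniform headings."""
        pos = geometry.uniform(rng, n)
        speeds = rng.uniform(*speed_range, size=n)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        vel = np.column_stack([speeds * np.cos(theta), speeds * np.sin(theta)])
        return cls(pos, vel)

    def copy(self) -> "AgentState":
        return AgentState(self.positions.copy(), self.velocities.copy())

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.velocities, axis=1)


# ---------------------------------------------------------------------------
# pair interaction (closed forms)
# ---------------------------------------------------------------------------

def pair_potential(d: np.ndarray, params: SocialParams) -> np.ndarray:
    """Pair potential Cr e^{-d/lr} - Ca e^{-d/la}."""
    p = params
    d = np.asarray(d, dtype=float)
    return (p.repulsion_strength * np.exp(-d / p.repulsion_length)
            - p.attraction_strength * np.exp(-d / p.attraction_length))


def pair_force_coeff(d: np.ndarray, params: SocialParams) -> np.ndarray:
    """Radial force coefficient (positive = repulsive): -dU/dd."""
    p = params
    d = np.asarray(d, dtype=float)
    return ((p.repulsion_strength / p.repulsion_length) * np.exp(-d / p.repulsion_length)
            - (p.attraction_strength / p.attraction_length) * np.exp(-d / p.attraction_length))


def force_balance_distance(params: SocialParams) -> float:
    """Separation d* at which the pair force changes sign (repulsion->attraction)."""
    p = params
    num = np.log((p.repulsion_strength / p.repulsion_length)
                 / (p.attraction_strength / p.attraction_length))
    return float(num / (1.0 / p.repulsion_length - 1.0 / p.attraction_length))


# ---------------------------------------------------------------------------
# reference (numpy) operations
# ---------------------------------------------------------------------------

def neighbor_sets(
    state: AgentState,
    traits: Traits,
    params: SocialParams,
    geometry: TorusGeometry,
) -> list[np.ndarray]:
    """Brute-force k-NN within each agent's ``lmax``: for each agent, up to k
    others sorted by minimum-image distance ascending (ties by index)."""
    d = geometry.pairwise_distances(state.positions)
    n = state.n
    k = params.neighbor_count
    out: list[np.ndarray] = []
    idx = np.arange(n)
    for i in range(n):
        mask = (d[i] <= traits.lmax[i]) & (idx != i)
        cand = idx[mask]
        order = np.lexsort((cand, d[i][cand]))  # distance, then index
        out.append(cand[order][:k])
    return out


def neighbor_arrays(
    state: AgentState, traits: Traits, params: SocialParams, geometry: TorusGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel-backed neighbour lists: (nbr, counts) with nbr[i, :counts[i]] valid."""
    return _kernels.knn_neighbors(
        state.positions, geometry.edge_length,
        np.broadcast_to(traits.lmax, (state.n,)).astype(float),
        int(params.neighbor_count),
    )


def social_force(
    i: int,
    state: AgentState,
    neighbors: np.ndarray,
    params: SocialParams,
    geometry: TorusGeometry,
) -> np.ndarray:
    """Social force on agent ``i`` from its neighbour list (reference path)."""
    neighbors = np.asarray(neighbors, dtype=int)
    if neighbors.size == 0:
        return np.zeros(2)
    delta = geometry.delta(state.positions[i], state.positions[neighbors])  # from j toward i
    d = np.linalg.norm(delta, axis=1)
    keep = d >= _kernels.EPS_COINCIDENT
    if not np.any(keep):
        return np.zeros(2)
    delta, d = delta[keep], d[keep]
    coeff = pair_force_coeff(d, params)
    return (coeff / d) @ delta


def response_speed_param(psi0: float, psi1: float, s_value: float) -> float:
    """Preferred-speed parameter Psi = psi0 - psi1 * S; may be negative."""
    return psi0 - psi1 * s_value


def autonomous_force(psi: float, velocity: np.ndarray, params: SocialParams) -> np.ndarray:
    """Self-propulsion force (Psi - eta |v|^2) v/|v|; zero below the speed floor."""
    v = np.asarray(velocity, dtype=float)
    speed = float(np.linalg.norm(v))
    if speed < _kernels.EPS_SPEED:
        return np.zeros(2)
    return (psi - params.damping * speed**2) * v / speed


def step(
    state: AgentState,
    traits: Traits,
    params: SocialParams,
    field: ResourceField | None,
    rng: np.random.Generator,
    geometry: TorusGeometry | None = None,
) -> tuple[AgentState, np.ndarray]:
    """One synchronous time step; returns the new state and the per-agent
    resource values sampled at the start of the step."""
    geometry = geometry or (field.geometry if field is not None else TorusGeometry())
    n = state.n
    if field is not None and field.peaks:
        s = np.asarray(field.value(state.positions), dtype=float)
    else:
        s = np.zeros(n)
    psi = traits.psi0 - traits.psi1 * s
    headings = rng.uniform(0.0, 2.0 * np.pi, size=n) if params.noise_magnitude > 0 else np.zeros(n)
    pos = state.positions.copy()
    vel = state.velocities.copy()
    _kernels.advance(
        pos, vel, psi,
        np.broadcast_to(traits.lmax, (n,)).astype(float),
        params.repulsion_strength, params.attraction_strength,
        params.repulsion_length, params.attraction_length,
        int(params.neighbor_count), params.mass, params.damping,
        params.time_step, int(params.n_sub), params.noise_magnitude,
        headings, geometry.edge_length,
    )
    bad = np.flatnonzero(~np.all(np.isfinite(pos) & np.isfinite(vel), axis=1))
    if bad.size:
        raise FloatingPointError(f"non-finite state after update for agent index {bad[0]}")
    return AgentState(pos, vel), s


def interaction_graph(
    state: AgentState,
    traits: Traits,
    params: SocialParams,
    geometry: TorusGeometry,
) -> tuple[nx.Graph, list[set[int]]]:
    """Undirected social network: edge {i, j} if either influences the other.

    Returns the graph and its connected components (the 'groups')."""
    nbr, counts = neighbor_arrays(state, traits, params, geometry)
    g = nx.Graph()
    g.add_nodes_from(range(state.n))
    for i in range(state.n):
        for j in nbr[i, : counts[i]]:
            g.add_edge(i, int(j))
    comps = [set(c) for c in nx.connected_components(g)]
    return g, comps


def group_label_array(
    state: AgentState, traits: Traits, params: SocialParams, geometry: TorusGeometry
) -> np.ndarray:
    """Fast per-agent group labels (same partition as ``interaction_graph``)."""
    nbr, counts = neighbor_arrays(state, traits, params, geometry)
    return _kernels.group_labels(nbr, counts)


def with_noise(params: SocialParams, gamma: float) -> SocialParams:
    """Convenience: copy of ``params`` with a different noise magnitude."""
    return replace(params, noise_magnitude=gamma)
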