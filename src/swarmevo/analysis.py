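"""Order parameters, sweep protocols, and collective-computation metrics.

The central order parameter is the mean distance to the 10 nearest neighbours
averaged over the population, <d10NN> — an inverse proxy for local density
that separates the three collective states (station-keeping / cohesive /
dispersed) and exhibits hysteresis when the preferred-speed parameter Psi is
swept slowly down and back up.  The collective-computation metrics quantify
how well a population maps the resource field: the Kullback-Leibler
divergence between the (radially binned) resource distribution and agent
density around a peak, the time course of arrivals at a peak with linear
(constant-rate) versus exponential fits, and the matching of group sizes to
peak masses.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _kernels
from .dynamics import (
    AgentState,
    SocialParams,
    Traits,
    group_label_array,
    neighbor_arrays,
    pair_potential,
)
from .environment import ResourceField, peak_mass
from .geometry import TorusGeometry
from .simulate import simulate

__all__ = [
    "SweepResult",
    "ArrivalCurve",
    "mean_dist_knn",
    "potential_energy",
    "hysteresis_sweep",
    "phase_sweep",
    "phase_boundary",
    "kl_divergence_to_resource",
    "arrival_counts",
    "fit_arrival",
    "arrival_curve",
    "group_peak_matching",
    "classify_state",
    "transition_edges",
]


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

def mean_dist_knn(
    state: AgentState | np.ndarray,
    geometry: TorusGeometry,
    n_neighbors: int = 10,
) -> float:
    """<d_kNN>: per-agent mean minimum-image distance to its ``n_neighbors``
    nearest others (no interaction-range cutoff), averaged over all agents."""
    pos = state.positions if isinstance(state, AgentState) else np.asarray(state, dtype=float)
    if pos.shape[0] <= n_neighbors:
        raise ValueError(f"need more than {n_neighbors} agents")
    return float(_kernels.mean_knn_distance(pos, geometry.edge_length, int(n_neighbors)))


def potential_energy(
    state: AgentState,
    traits: Traits,
    params: SocialParams,
    geometry: TorusGeometry,
) -> float:
    """Mean over agents of the pair potential summed over each agent's
    neighbour set."""
    nbr, counts = neighbor_arrays(state, traits, params, geometry)
    total = 0.0
    for i in range(state.n):
        c = counts[i]
        if c == 0:
            continue
        d = geometry.distance(state.positions[i], state.positions[nbr[i, :c]])
        total += float(np.sum(pair_potential(d, params)))
    return total / state.n


def classify_state(psi: np.ndarray, lower: float = 0.0, upper: float = 2.95) -> np.ndarray:
    """Label agents by instantaneous Psi: station-keeping (Psi <= lower),
    cohesive (lower < Psi <= upper), dispersed (Psi > upper)."""
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    labels = np.where(psi <= lower, "station-keeping",
                      np.where(psi <= upper, "cohesive", "dispersed"))
    return labels


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Order parameters along a control-parameter grid, per replicate."""

    control: str
    grid: np.ndarray  # control values in sweep order
    direction: str  # "decreasing" | "increasing"
    d_knn: np.ndarray  # shape (n_grid, n_replicates)
    extras: dict = dataclass_field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return self.d_knn.mean(axis=1)

    @property
    def sem2(self) -> np.ndarray:
        """Two standard errors over replicates."""
        n = self.d_knn.shape[1]
        return 2.0 * self.d_knn.std(axis=1, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(len(self.grid))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gi, g in enumerate(self.grid):
            for r in range(self.d_knn.shape[1]):
                rows.append({"control": self.control, "value": float(g),
                             "direction": self.direction, "replicate": r,
                             "d10nn": float(self.d_knn[gi, r])})
        return pd.DataFrame(rows)


def _psi_grid(start: float, end: float, step: float) -> np.ndarray:
    n = int(round(abs(end - start) / step))
    return np.round(np.linspace(start, end, n + 1), 10)


def hysteresis_sweep(
    params: SocialParams,
    n_agents: int,
    rng: np.random.Generator,
    psi_start: float = 4.0,
    psi_end: float = -1.0,
    psi_step: float = 0.2,
    equilibration_steps: int = 5000,
    replicates: int = 1,
    geometry: TorusGeometry | None = None,
    lmax: float = 30.0,
    n_neighbors: int = 10,
) -> tuple[SweepResult, SweepResult]:
    """Hysteresis protocol in a uniform (resource-free) environment.

    Within each replicate the population starts dispersed at ``psi_start``;
    at each grid value it equilibrates for ``equilibration_steps`` and
    <d10NN> is measured, carrying the agent state to the next grid value.
    The grid runs down to ``psi_end`` and back up.  Psi is imposed uniformly
    via psi0 = Psi, psi1 = 0.  Returns (decreasing, increasing) branches.
    """
    geometry = geometry or TorusGeometry()
    down = _psi_grid(psi_start, psi_end, psi_step)
    up = down[::-1].copy()
    d_down = np.empty((len(down), replicates))
    d_up = np.empty((len(up), replicates))
    for r in range(replicates):
        state = AgentState.random(rng, n_agents, geometry)
        for branch, grid, out in (("down", down, d_down), ("up", up, d_up)):
            for gi, psi in enumerate(grid):
                traits = Traits.uniform(n_agents, psi, 0.0, lmax)
                res = simulate(state, traits, params, None, equilibration_steps, rng,
                               geometry=geometry)
                state = res.state
                out[gi, r] = mean_dist_knn(state, geometry, n_neighbors)
    return (
        SweepResult("Psi", down, "decreasing", d_down),
        SweepResult("Psi", up, "increasing", d_up),
    )


def transition_edges(down: SweepResult, up: SweepResult) -> tuple[float, float]:
    """Empirical edges of the transitional regime from a hysteresis pair.

    Returns (lower_edge, upper_edge): the Psi at which the decreasing branch
    shows its largest single-step *drop* of <d10NN>, and the Psi at which the
    increasing branch shows its largest single-step *jump*.  Each reported
    Psi is the grid value at which the changed order parameter is first
    observed.
    """
    dm = down.mean
    lower = float(down.grid[int(np.argmin(np.diff(dm))) + 1])
    um = up.mean
    upper = float(up.grid[int(np.argmax(np.diff(um))) + 1])
    return lower, upper


_PHASE_PARAMS = {
    "Ca": "attraction_strength",
    "k": "neighbor_count",
    "la": "attraction_length",
}


def phase_sweep(
    param_name: str,
    param_values: np.ndarray,
    psi0_values: np.ndarray,
    params: SocialParams,
    n_agents: int,
    rng: np.random.Generator,
    steps: int = 2000,
    replicates: int = 1,
    geometry: TorusGeometry | None = None,
    lmax: float = 30.0,
) -> pd.DataFrame:
    """<d10NN> surface over (social parameter, psi0) in a uniform environment.

    Each grid point simulates an independent population for ``steps`` time
    steps from random initial conditions.  ``param_name`` is one of
    ``"Ca"``, ``"k"``, ``"la"`` (or the corresponding field name).
    """
    from dataclasses import replace

    field_name = _PHASE_PARAMS.get(param_name, param_name)
    geometry = geometry or TorusGeometry()
    rows = []
    for pv in param_values:
        p = replace(params, **{field_name: type(getattr(params, field_name))(pv)})
        for psi0 in psi0_values:
            traits = Traits.uniform(n_agents, float(psi0), 0.0, lmax)
            for r in range(replicates):
                state = AgentState.random(rng, n_agents, geometry)
                res = simulate(state, traits, p, None, steps, rng, geometry=geometry)
                rows.append({"param": param_name, "param_value": float(pv),
                             "psi0": float(psi0), "replicate": r,
                             "d10nn": mean_dist_knn(res.state, geometry)})
    return pd.DataFrame(rows)


def phase_boundary(sweep: pd.DataFrame) -> pd.DataFrame:
    """Empirical cohesive-dispersed boundary: for each social-parameter value,
    the psi0 of steepest increase of <d10NN> along the psi0 axis."""
    rows = []
    for pv, grp in sweep.groupby("param_value"):
        curve = grp.groupby("psi0")["d10nn"].mean().sort_index()
        psi0 = curve.index.to_numpy()
        diffs = np.diff(curve.to_numpy())
        j = int(np.argmax(diffs))
        rows.append({"param_value": float(pv),
                     "psi0_boundary": float(0.5 * (psi0[j] + psi0[j + 1]))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# collective computation metrics
# ---------------------------------------------------------------------------

def kl_divergence_to_resource(
    state: AgentState | np.ndarray,
    field: ResourceField,
    peak_index: int = 0,
    n_bins: int = 30,
    r_max: float | None = None,
    eps_bin: float = 1e-9,
) -> float:
    """KL(resource || agent density) over radial annuli about a peak centre.

    Both distributions are binned on the same annuli (default 30 bins out to
    3 decay lengths), normalized to probabilities after adding ``eps_bin``
    to every bin, and compared in nats.  Zero iff the binned distributions
    coincide (within regularization)."""
    pos = state.positions if isinstance(state, AgentState) else np.atleast_2d(state)
    peak = field.peaks[peak_index]
    if r_max is None:
        r_max = 3.0 * peak.decay_length
    edges = np.linspace(0.0, r_max, n_bins + 1)
    d = field.geometry.distance(pos, peak.centroid)
    agent_counts, _ = np.histogram(d, bins=edges)
    # resource mass in each annulus: lam0 pi lam1^2 (e^{-r0^2/l^2} - e^{-r1^2/l^2})
    lam1sq = peak.decay_length**2
    shell = np.exp(-edges[:-1] ** 2 / lam1sq) - np.exp(-edges[1:] ** 2 / lam1sq)
    resource_mass = peak.amplitude * np.pi * lam1sq * shell
    if agent_counts.sum() == 0 or resource_mass.sum() == 0:
        raise ValueError("zero total mass in a binned distribution")
    p = resource_mass + eps_bin
    q = agent_counts + eps_bin
    return float(stats.entropy(p, q))  # KL(p || q) in nats


@dataclass
class ArrivalCurve:
    """Agent count near a peak centre over time, with model fits."""

    times: np.ndarray
    counts: np.ndarray
    linear: dict = dataclass_field(default_factory=dict)  # kappa_a, intercept, rss, aic
    exponential: dict = dataclass_field(default_factory=dict)  # kappa_s1, kappa_s2, rss, aic
    preferred: str | None = None  # "linear" | "exponential" | None
    degenerate: bool = False
    fit_slice: slice | None = None


def arrival_counts(
    snapshots: list[AgentState] | list[np.ndarray],
    center: np.ndarray,
    radius: float,
    geometry: TorusGeometry,
) -> np.ndarray:
    """Per-snapshot count of agents within ``radius`` of ``center``."""
    out = np.empty(len(snapshots), dtype=np.int64)
    for t, s in enumerate(snapshots):
        pos = s.positions if isinstance(s, AgentState) else np.atleast_2d(s)
        out[t] = int(np.count_nonzero(geometry.distance(pos, center) <= radius))
    return out


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + 2 * k


def fit_arrival(
    times: np.ndarray,
    counts: np.ndarray,
    rise_fraction: float = 0.95,
) -> ArrivalCurve:
    """Fit linear (kappa_a * t + c) and exponential (kappa_s1 + exp(kappa_s2 t))
    models to an arrival-count series.

    The fit window runs from t=0 until the count first reaches
    ``rise_fraction`` of its maximum (the exponential form has no saturation
    term, so the plateau after a peak fills up is excluded).  The preferred
    model is the one with the lower AIC; a flat series is flagged degenerate.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts, dtype=float)
    curve = ArrivalCurve(times=times, counts=counts)
    if counts.max() == counts.min():
        curve.degenerate = True
        return curve
    thresh = counts.min() + rise_fraction * (counts.max() - counts.min())
    end = int(np.argmax(counts >= thresh)) + 1
    end = max(end, 5)  # need a handful of points to fit two parameters
    sl = slice(0, min(end, len(times)))
    curve.fit_slice = sl
    t, c = times[sl], counts[sl]
    n = len(t)

    slope, intercept = np.polyfit(t, c, 1)
    rss_lin = float(np.sum((c - (slope * t + intercept)) ** 2))
    curve.linear = {"kappa_a": float(slope), "intercept": float(intercept),
                    "rss": rss_lin, "aic": _aic(rss_lin, n, 2)}

    def model(tt, k1, k2):
        return k1 + np.exp(np.clip(k2 * tt, -50.0, 50.0))

    span = max(c.max() - c.min(), 2.0)
    k2_guess = np.log(span) / max(t[-1], 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model, t, c, p0=(max(c[0] - 1.0, 0.0), k2_guess),
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
        rss_exp = float(np.sum((c - model(t, *popt)) ** 2))
        curve.exponential = {"kappa_s1": float(popt[0]), "kappa_s2": float(popt[1]),
                             "rss": rss_exp, "aic": _aic(rss_exp, n, 2)}
        curve.preferred = ("exponential"
                           if curve.exponential["aic"] < curve.linear["aic"] else "linear")
    except RuntimeError:
        curve.preferred = "linear"
    return curve


def arrival_curve(
    snapshots: list[AgentState],
    times: np.ndarray,
    field: ResourceField,
    peak_index: int = 0,
    radius: float | None = None,
    rise_fraction: float = 0.95,
) -> ArrivalCurve:
    """Count agents within one decay length of a designated peak centre over
    time and fit the linear and exponential arrival models."""
    peak = field.peaks[peak_index]
    r = peak.decay_length if radius is None else radius
    counts = arrival_counts(snapshots, peak.centroid, r, field.geometry)
    return fit_arrival(np.asarray(times, dtype=float), counts, rise_fraction)


def _circular_mean(coords: np.ndarray, L: float) -> float:
    theta = coords * (2.0 * np.pi / L)
    x = np.mean(np.cos(theta))
    y = np.mean(np.sin(theta))
    return float((np.arctan2(y, x) % (2.0 * np.pi)) * L / (2.0 * np.pi))


def group_centroids(
    state: AgentState, traits: Traits, params: SocialParams, geometry: TorusGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Torus centroids (circular mean per coordinate) and sizes of every group."""
    labels = group_label_array(state, traits, params, geometry)
    uniq = np.unique(labels)
    cents = np.empty((uniq.size, 2))
    sizes = np.empty(uniq.size, dtype=np.int64)
    for gi, lab in enumerate(uniq):
        members = state.positions[labels == lab]
        cents[gi] = [_circular_mean(members[:, 0], geometry.edge_length),
                     _circular_mean(members[:, 1], geometry.edge_length)]
        sizes[gi] = members.shape[0]
    return cents, sizes


def group_peak_matching(
    snapshots: list[AgentState],
    traits: Traits,
    params: SocialParams,
    field: ResourceField,
) -> pd.DataFrame:
    """Per peak: time-averaged size of the nearest group versus peak mass.

    For each snapshot in the averaging window, the group whose torus centroid
    is closest (minimum image) to each peak centre contributes its size; the
    returned table pairs the time-mean with the peak's integrated mass."""
    geometry = field.geometry
    masses = [peak_mass(p) for p in field.peaks]
    sums = np.zeros(len(field.peaks))
    for s in snapshots:
        cents, sizes = group_centroids(s, traits, params, geometry)
        if cents.size == 0:
            continue
        for pi, p in enumerate(field.peaks):
            d = geometry.distance(cents, p.centroid)
            sums[pi] += sizes[int(np.argmin(d))]
    n = max(len(snapshots), 1)
    return pd.DataFrame({
        "peak": np.arange(len(field.peaks)),
        "peak_mass": masses,
        "mean_group_size": sums / n,
    })
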