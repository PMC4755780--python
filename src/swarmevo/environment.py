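"""Dynamic multi-peak resource landscapes on a periodic domain.

The resource is a sum of ``M`` Gaussian peaks,

    S(x) = sum_p  lam0_p * exp(-|x - c_p|^2 / lam1_p^2),

with ``lam0`` the value at the peak centre and ``lam1`` the decay length.
Peak centroids perform Brownian motion with drift ``alpha`` and per-component
standard deviation ``beta`` per time step; independently each peak relocates
(teleports to a uniform random site, amplitude restored to its initial value)
with probability ``1/tau_p`` per step.  An optional depletion variant lets
agents consume resource at rate ``u * S(x_i)`` per step, drawing down peak
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Sequence

import numpy as np

from .geometry import TorusGeometry

__all__ = [
    "ResourcePeak",
    "ResourceField",
    "field_value",
    "step_peaks",
    "deplete",
    "peak_mass",
]


@dataclass
class ResourcePeak:
    """A single Gaussian resource peak.

    ``amplitude`` may fall below ``initial_amplitude`` only through depletion;
    relocation restores it.
    """

    centroid: np.ndarray
    amplitude: float = 10.0
    decay_length: float = 20.0
    initial_amplitude: float | None = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(2)
        if self.initial_amplitude is None:
            self.initial_amplitude = float(self.amplitude)
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")


def peak_mass(peak: ResourcePeak) -> float:
    """Integral of a peak's value over the plane: lam0 * pi * lam1**2.

    Exact for the infinite plane; for ``decay_length`` much smaller than the
    domain edge the periodic images contribute negligibly.
    """
    return float(peak.amplitude) * np.pi * float(peak.decay_length) ** 2


@dataclass
class ResourceField:
    """``M`` Gaussian peaks plus their motion/relocation/depletion dynamics."""

    peaks: list[ResourcePeak]
    geometry: TorusGeometry = dataclass_field(default_factory=TorusGeometry)
    drift: np.ndarray = dataclass_field(default_factory=lambda: np.array([1.0, 0.0]))
    diffusion_sd: float = 0.1
    relocation_timescale: float = 1500.0
    depletion_rate: float = 0.0

    def __post_init__(self) -> None:
        self.drift = np.asarray(self.drift, dtype=float).reshape(2)
        if self.relocation_timescale <= 0:
            raise ValueError("relocation_timescale must be > 0")
        if self.diffusion_sd < 0:
            raise ValueError("diffusion_sd must be >= 0")
        if self.depletion_rate < 0:
            raise ValueError("depletion_rate must be >= 0")
        for p in self.peaks:
            p.centroid = self.geometry.wrap(p.centroid)

    # -- array views used by the hot loops -------------------------------
    @property
    def centroids(self) -> np.ndarray:
        return np.array([p.centroid for p in self.peaks]).reshape(-1, 2)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p.amplitude for p in self.peaks], dtype=float)

    @property
    def decay_lengths(self) -> np.ndarray:
        return np.array([p.decay_length for p in self.peaks], dtype=float)

    # -- queries ---------------------------------------------------------
    def value(self, x: np.ndarray) -> np.ndarray | float:
        """Total resource value at position(s) ``x`` (last axis = xy)."""
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("positions must be finite")
        scalar = x.ndim == 1
        pts = np.atleast_2d(x)
        out = np.zeros(pts.shape[0])
        if self.peaks:
            d2 = self.per_peak_d2(pts)
            out = self.per_peak_values(d2).sum(axis=1)
        return float(out[0]) if scalar else out

    def per_peak_d2(self, pts: np.ndarray) -> np.ndarray:
        """Squared minimum-image distances, shape (n_points, M)."""
        delta = self.geometry.delta(pts[:, None, :], self.centroids[None, :, :])
        return np.einsum("ijk,ijk->ij", delta, delta)

    def per_peak_values(self, d2: np.ndarray) -> np.ndarray:
        return self.amplitudes[None, :] * np.exp(-d2 / self.decay_lengths[None, :] ** 2)

    def total_mass(self) -> float:
        return sum(peak_mass(p) for p in self.peaks)

    # -- dynamics --------------------------------------------------------
    def step(self, rng: np.random.Generator) -> None:
        """Advance peak positions by one time step (in place).

        Each centroid is displaced by ``drift`` plus an isotropic Gaussian
        increment (per-component sd ``diffusion_sd``), then with probability
        ``1/relocation_timescale`` relocated uniformly with its amplitude
        reset to the initial value.
        """
        g = self.geometry
        for p in self.peaks:
            inc = self.drift + rng.normal(0.0, self.diffusion_sd, size=2)
            p.centroid = g.wrap(p.centroid + inc)
            if rng.random() < 1.0 / self.relocation_timescale:
                p.centroid = g.uniform(rng, 1)[0]
                p.amplitude = float(p.initial_amplitude)

    def deplete(self, agent_positions: np.ndarray, consumption_rate: float | None = None) -> np.ndarray:
        """Consume resource at each agent position (in place).

        Agent ``i`` consumes ``u * S(x_i)``; the draw-down is attributed to
        peaks in proportion to their contribution to ``S(x_i)`` and peak
        amplitudes floor at zero.  Returns per-agent consumed amounts.
        """
        u = self.depletion_rate if consumption_rate is None else float(consumption_rate)
        if u < 0:
            raise ValueError("consumption rate must be >= 0")
        pts = np.atleast_2d(np.asarray(agent_positions, dtype=float))
        n = pts.shape[0]
        if u == 0.0 or not self.peaks:
            return np.zeros(n)
        per_peak = self.per_peak_values(self.per_peak_d2(pts))  # (n, M)
        s_tot = per_peak.sum(axis=1)
        consumed = u * s_tot
        # attribution shares; agents with S=0 consume nothing
        with np.errstate(invalid="ignore", divide="ignore"):
            shares = np.where(s_tot[:, None] > 0, per_peak / s_tot[:, None], 0.0)
        per_peak_draw = (consumed[:, None] * shares).sum(axis=0)
        for p, draw in zip(self.peaks, per_peak_draw):
            p.amplitude = max(0.0, p.amplitude - float(draw))
        return consumed

    # -- export ----------------------------------------------------------
    def as_grid(self, resolution: int = 64) -> "pandas.DataFrame":  # noqa: F821
        """Dense field snapshot as a tidy table (x, y, S), x-fastest, units of lr."""
        import pandas as pd

        L = self.geometry.edge_length
        coords = (np.arange(resolution) + 0.5) * (L / resolution)
        yy, xx = np.meshgrid(coords, coords, indexing="ij")
        pts = np.column_stack([xx.ravel(), yy.ravel()])  # row-major, x-fastest
        s = self.value(pts)
        return pd.DataFrame({"x_lr": pts[:, 0], "y_lr": pts[:, 1], "S": s})


def make_field(
    rng: np.random.Generator,
    n_peaks: int = 2,
    amplitude: float = 10.0,
    decay_length: float = 20.0,
    geometry: TorusGeometry | None = None,
    drift: Sequence[float] = (1.0, 0.0),
    diffusion_sd: float = 0.1,
    relocation_timescale: float = 1500.0,
    depletion_rate: float = 0.0,
    centroids: np.ndarray | None = None,
) -> ResourceField:
    """Convenience constructor: ``n_peaks`` identical peaks, centroids uniform
    unless given explicitly."""
    geometry = geometry or TorusGeometry()
    if centroids is None:
        centroids = geometry.uniform(rng, n_peaks)
    peaks = [ResourcePeak(c, amplitude, decay_length) for c in np.atleast_2d(centroids)[:n_peaks]]
    return ResourceField(
        peaks,
        geometry=geometry,
        drift=np.asarray(drift, dtype=float),
        diffusion_sd=diffusion_sd,
        relocation_timescale=relocation_timescale,
        depletion_rate=depletion_rate,
    )


# Functional aliases matching the operation-style API.
def field_value(field: ResourceField, x: np.ndarray) -> np.ndarray | float:
    return field.value(x)


def step_peaks(field: ResourceField, rng: np.random.Generator) -> ResourceField:
    field.step(rng)
    return field


def deplete(field: ResourceField, agent_positions: np.ndarray, consumption_rate: float) -> np.ndarray:
    return field.deplete(agent_positions, consumption_rate)
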