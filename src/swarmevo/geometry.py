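"""Periodic 2-D geometry: the torus on which agents and resource peaks live.

All positions are stored in ``[0, L)`` per coordinate, with ``L`` the edge
length in units of the repulsion length scale ``lr``.  Displacements and
distances use the minimum-image convention, so each component of a
displacement has magnitude at most ``L/2`` and no distance can exceed
``L/sqrt(2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TorusGeometry"]


@dataclass(frozen=True)
class TorusGeometry:
    """Square periodic domain of edge length ``edge_length`` (units of lr)."""

    edge_length: float = 346.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.edge_length) or self.edge_length <= 0:
            raise ValueError(f"edge_length must be positive and finite, got {self.edge_length}")

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Map coordinates into ``[0, L)`` (works for any real input)."""
        w = np.mod(np.asarray(x, dtype=float), self.edge_length)
        # np.mod of a tiny negative value can round up to exactly L
        return np.where(w >= self.edge_length, 0.0, w)

    def delta(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image displacement ``a - b`` (broadcasts like numpy)."""
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        L = self.edge_length
        return d - L * np.round(d / L)

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image Euclidean distance between points (last axis = xy)."""
        return np.linalg.norm(self.delta(a, b), axis=-1)

    def pairwise_deltas(self, points: np.ndarray) -> np.ndarray:
        """All minimum-image displacements ``points[i] - points[j]``, shape (n, n, 2)."""
        p = np.asarray(points, dtype=float)
        return self.delta(p[:, None, :], p[None, :, :])

    def pairwise_distances(self, points: np.ndarray) -> np.ndarray:
        """Dense minimum-image distance matrix, shape (n, n)."""
        return np.linalg.norm(self.pairwise_deltas(points), axis=-1)

    def uniform(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """``n`` points drawn uniformly on the torus, shape (n, 2)."""
        return rng.uniform(0.0, self.edge_length, size=(n, 2))
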