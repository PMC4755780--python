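import numpy as np
import pytest

from swarmevo.dynamics import AgentState, SocialParams, Traits
from swarmevo.geometry import TorusGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def geometry():
    return TorusGeometry(100.0)


@pytest.fixture
def params():
    return SocialParams()


@pytest.fixture
def quiet_params():
    """Noise-free parameters for deterministic trajectories."""
    return SocialParams(noise_magnitude=0.0)


def random_state(rng, n, geometry, speed=0.5):
    pos = geometry.uniform(rng, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    vel = speed * np.column_stack([np.cos(theta), np.sin(theta)])
    return AgentState(pos, vel)


@pytest.fixture
def make_state(geometry):
    def _make(rng, n, speed=0.5, geom=None):
        return random_state(rng, n, geom or geometry, speed)

    return _make


def brute_force_neighbors(positions, lmax, k, geometry):
    """Independent all-pairs neighbour oracle (lexsort on distance, index)."""
    d = geometry.pairwise_distances(positions)
    n = positions.shape[0]
    idx = np.arange(n)
    out = []
    for i in range(n):
        mask = (d[i] <= lmax[i]) & (idx != i)
        cand = idx[mask]
        order = np.lexsort((cand, d[i][cand]))
        out.append(cand[order][:k])
    return out
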