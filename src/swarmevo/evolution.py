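"""Generational evolutionary loop over the heritable traits (psi0, psi1, lmax).

Each generation: N agents are placed uniformly at random with small random
velocities, live ``steps_per_generation`` time steps in the (persistent by
default) resource landscape, and are scored by the mean resource value they
experienced.  Offspring parentage is sampled with probability proportional to
relative fitness; each offspring inherits its parent's traits perturbed by
independent Gaussian mutations (interaction range clipped to [0, 30]).  The
asocial control pins ``lmax`` between the repulsion and attraction length
scales, so agents repel at contact but never attract.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .dynamics import LMAX_CAP, AgentState, SocialParams, Traits
from .environment import ResourceField
from .simulate import simulate

__all__ = [
    "EvolutionConfig",
    "GenerationRecord",
    "lifetime_fitness",
    "select_and_reproduce",
    "mutate",
    "run_evolution",
    "invasion_experiment",
    "default_initial_traits",
]


@dataclass(frozen=True)
class EvolutionConfig:
    population_size: int = 500
    generations: int = 100
    steps_per_generation: int = 1500
    sigma_psi0: float = 0.05
    sigma_psi1: float = 0.05
    sigma_lmax: float = 0.5
    psi0_bounds: tuple[float, float] | None = None
    psi1_bounds: tuple[float, float] | None = None
    lmax_bounds: tuple[float, float] = (0.0, LMAX_CAP)
    asocial_mode: bool = False
    lmax_asocial: float = 2.0
    reset_environment: bool = False
    speed_range: tuple[float, float] = (0.0, 0.1)

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1 or self.steps_per_generation < 1:
            raise ValueError("generations and steps_per_generation must be >= 1")
        if min(self.sigma_psi0, self.sigma_psi1, self.sigma_lmax) < 0:
            raise ValueError("mutation standard deviations must be >= 0")


@dataclass
class GenerationRecord:
    """Trait and fitness summary of one generation (traits are pre-selection)."""

    generation: int
    traits: Traits
    fitness: np.ndarray
    lineage: np.ndarray | None = None

    @property
    def mean_fitness(self) -> float:
        return float(np.mean(self.fitness))

    @property
    def fitness_cv(self) -> float:
        """Coefficient of variation sd/mean; nan when the mean is zero."""
        m = self.mean_fitness
        return float(np.std(self.fitness) / m) if m > 0 else float("nan")

    @property
    def trait_means(self) -> dict[str, float]:
        return {
            "psi0": float(np.mean(self.traits.psi0)),
            "psi1": float(np.mean(self.traits.psi1)),
            "lmax": float(np.mean(self.traits.lmax)),
        }

    def summary_row(self) -> dict[str, float]:
        row = {"generation": self.generation, "mean_fitness": self.mean_fitness,
               "fitness_cv": self.fitness_cv}
        row.update({f"mean_{k}": v for k, v in self.trait_means.items()})
        if self.lineage is not None:
            row["invader_freq"] = float(np.mean(self.lineage == 1))
        return row


def lifetime_fitness(s_samples: np.ndarray) -> float:
    """Fitness of one agent: arithmetic mean of the resource it experienced."""
    s = np.asarray(s_samples, dtype=float)
    if s.size == 0:
        raise ValueError("fitness requires at least one recorded step")
    return float(np.mean(s))


def select_and_reproduce(
    fitnesses: np.ndarray, rng: np.random.Generator, n_offspring: int | None = None
) -> np.ndarray:
    """Fitness-proportional parentage: ``n_offspring`` i.i.d. parent indices.

    When every fitness is zero, parents are drawn uniformly.
    """
    f = np.asarray(fitnesses, dtype=float)
    if np.any(f < 0):
        raise ValueError("fitnesses must be non-negative")
    n = f.size if n_offspring is None else int(n_offspring)
    total = f.sum()
    p = None if total == 0 else f / total
    return rng.choice(f.size, size=n, replace=True, p=p)


def _clip(x: np.ndarray, bounds: tuple[float, float] | None) -> np.ndarray:
    return x if bounds is None else np.clip(x, *bounds)


def mutate(parent_traits: Traits, config: EvolutionConfig, rng: np.random.Generator) -> Traits:
    """Gaussian mutation of each trait; lmax clipped (or pinned in asocial mode)."""
    n = len(parent_traits)
    psi0 = _clip(parent_traits.psi0 + rng.normal(0.0, config.sigma_psi0, n)
                 if config.sigma_psi0 > 0 else parent_traits.psi0.copy(), config.psi0_bounds)
    psi1 = _clip(parent_traits.psi1 + rng.normal(0.0, config.sigma_psi1, n)
                 if config.sigma_psi1 > 0 else parent_traits.psi1.copy(), config.psi1_bounds)
    if config.asocial_mode:
        lmax = np.full(n, config.lmax_asocial)
    else:
        lmax = _clip(parent_traits.lmax + rng.normal(0.0, config.sigma_lmax, n)
                     if config.sigma_lmax > 0 else parent_traits.lmax.copy(), config.lmax_bounds)
    return Traits(psi0, psi1, lmax, cap=config.lmax_bounds[1])


def default_initial_traits(config: EvolutionConfig, rng: np.random.Generator) -> Traits:
    """Founding population: weakly responsive, weakly social phenotypes."""
    n = config.population_size
    psi0 = rng.uniform(0.5, 1.5, n)
    psi1 = rng.uniform(0.0, 0.5, n)
    if config.asocial_mode:
        lmax = np.full(n, config.lmax_asocial)
    else:
        lmax = rng.uniform(0.0, 5.0, n)
    return Traits(psi0, psi1, lmax, cap=config.lmax_bounds[1])


def run_evolution(
    config: EvolutionConfig,
    params: SocialParams,
    field: ResourceField,
    rng: np.random.Generator,
    initial_traits: Traits | None = None,
    lineage: np.ndarray | None = None,
    checkpoint_path: str | Path | None = None,
    checkpoint_every: int = 0,
) -> list[GenerationRecord]:
    """Run the full generational loop; returns one record per generation.

    The resource field evolves continuously across generations unless
    ``config.reset_environment`` is set (then peak centroids are redrawn
    uniformly and amplitudes restored each generation).  Agent positions and
    velocities are re-randomized every generation.
    """
    n = config.population_size
    traits = initial_traits.copy() if initial_traits is not None else default_initial_traits(config, rng)
    if len(traits) != n:
        raise ValueError("initial traits must match population_size")
    if config.asocial_mode and not np.all(traits.lmax == config.lmax_asocial):
        traits = Traits(traits.psi0, traits.psi1, np.full(n, config.lmax_asocial), traits.cap)
    if lineage is not None:
        lineage = np.asarray(lineage, dtype=int).copy()
        if lineage.size != n:
            raise ValueError("lineage labels must match population_size")

    records: list[GenerationRecord] = []
    for gen in range(config.generations):
        if config.reset_environment:
            for p in field.peaks:
                p.centroid = field.geometry.uniform(rng, 1)[0]
                p.amplitude = float(p.initial_amplitude)
        state = AgentState.random(rng, n, field.geometry, config.speed_range)
        result = simulate(state, traits, params, field, config.steps_per_generation, rng)
        fitness = result.mean_s
        rec = GenerationRecord(gen, traits.copy(), fitness.copy(),
                               None if lineage is None else lineage.copy())
        records.append(rec)

        parents = select_and_reproduce(fitness, rng, n)
        traits = mutate(
            Traits(traits.psi0[parents], traits.psi1[parents], traits.lmax[parents], traits.cap),
            config, rng,
        )
        if lineage is not None:
            lineage = lineage[parents]
        if checkpoint_path and checkpoint_every and (gen + 1) % checkpoint_every == 0:
            save_checkpoint(checkpoint_path, config, gen + 1, traits, field, rng, lineage)
    return records


def invasion_experiment(
    resident_traits: tuple[float, float, float],
    invader_traits: tuple[float, float, float],
    n_invaders: int,
    config: EvolutionConfig,
    params: SocialParams,
    field: ResourceField,
    rng: np.random.Generator,
) -> np.ndarray:
    """Invader-lineage frequency per generation, starting from ``n_invaders``
    invaders among ``N - n_invaders`` residents."""
    n = config.population_size
    if not (1 <= n_invaders < n):
        raise ValueError("need 1 <= n_invaders < population_size")
    lineage = np.zeros(n, dtype=int)
    lineage[:n_invaders] = 1
    def expand(tr):
        return np.where(lineage == 1, tr[0], tr[1])
    psi0 = expand((invader_traits[0], resident_traits[0]))
    psi1 = expand((invader_traits[1], resident_traits[1]))
    lmax = expand((invader_traits[2], resident_traits[2]))
    records = run_evolution(config, params, field, rng,
                            initial_traits=Traits(psi0, psi1, lmax), lineage=lineage)
    return np.array([float(np.mean(r.lineage == 1)) for r in records])


# ---------------------------------------------------------------------------
# checkpointing (JSON, full RNG state)
# ---------------------------------------------------------------------------

def save_checkpoint(path, config, generation, traits, field, rng, lineage=None) -> None:
    payload = {
        "config": asdict(config),
        "generation": int(generation),
        "traits": {"psi0": traits.psi0.tolist(), "psi1": traits.psi1.tolist(),
                   "lmax": traits.lmax.tolist()},
        "lineage": None if lineage is None else np.asarray(lineage).tolist(),
        "field": {
            "centroids": field.centroids.tolist(),
            "amplitudes": field.amplitudes.tolist(),
            "initial_amplitudes": [p.initial_amplitude for p in field.peaks],
            "decay_lengths": field.decay_lengths.tolist(),
        },
        "rng_state": rng.bit_generator.state,
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path, config: EvolutionConfig, field: ResourceField):
    """Restore (generation, traits, lineage, rng); validates the config and
    writes peak state back into ``field``."""
    payload = json.loads(Path(path).read_text())
    stored = payload["config"]
    current = asdict(config)
    # tuples round-trip through JSON as lists
    norm = lambda d: json.loads(json.dumps(d))
    if norm(stored) != norm(current):
        raise ValueError("checkpoint was produced under a different evolution config")
    t = payload["traits"]
    traits = Traits(np.array(t["psi0"]), np.array(t["psi1"]), np.array(t["lmax"]))
    lineage = None if payload["lineage"] is None else np.array(payload["lineage"], dtype=int)
    f = payload["field"]
    for p, c, a, a0 in zip(field.peaks, f["centroids"], f["amplitudes"], f["initial_amplitudes"]):
        p.centroid = np.asarray(c, dtype=float)
        p.amplitude = float(a)
        p.initial_amplitude = float(a0)
    rng = np.random.Generator(np.random.PCG64())
    rng.bit_generator.state = payload["rng_state"]
    return payload["generation"], traits, lineage, rng
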