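"""The mutation-replication-selection cycle.

One cycle applies three stages to the population:

1. **Mutation** — every member has exactly one uniformly chosen locus
   flipped (one substitution per genome per cycle).
2. **Replication** — the population expands to the expanded size by
   sampling parents with replacement, each parent weighted by its fitness
   index (count of 1 alleles). Offspring are exact copies. If every member
   has fitness 0 the sampling falls back to uniform weights.
3. **Selection** — a bottleneck back to the seed size via binary
   tournaments: for each survivor slot, two members of the expanded
   population are drawn independently with replacement and the fitter is
   kept; ties are broken by a fair coin.

After each selection the run terminates if any surviving member equals the
target genotype; the reported cycle count (mutational distance) is the
number of completed cycles at first detection. A target that appears
transiently among the expanded population but does not survive selection
does not terminate the run.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .core import (
    GenotypeLike,
    Population,
    RunResult,
    SimulationConfig,
    TrajectoryPoint,
    as_genotype,
)

__all__ = [
    "mutate_population",
    "replicate_population",
    "select_population",
    "run_to_target",
]


def _mutate(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n, L = arr.shape
    out = arr.copy()
    loci = rng.integers(0, L, size=n)
    out[np.arange(n), loci] ^= 1
    return out


def _replicate(arr: np.ndarray, rng: np.random.Generator, expanded_size: int) -> np.ndarray:
    fitness = arr.sum(axis=1).astype(np.float64)
    total = fitness.sum()
    if total == 0.0:
        weights = np.full(arr.shape[0], 1.0 / arr.shape[0])
    else:
        weights = fitness / total
    parents = rng.choice(arr.shape[0], size=expanded_size, p=weights)
    return arr[parents].copy()


def _select(arr: np.ndarray, rng: np.random.Generator, selected_size: int) -> np.ndarray:
    fitness = arr.sum(axis=1)
    first = rng.integers(0, arr.shape[0], size=selected_size)
    second = rng.integers(0, arr.shape[0], size=selected_size)
    first_wins = fitness[first] > fitness[second]
    tie = fitness[first] == fitness[second]
    coin = rng.random(selected_size) < 0.5
    winners = np.where(first_wins | (tie & coin), first, second)
    return arr[winners].copy()


def mutate_population(population: Population, rng: np.random.Generator) -> Population:
    """Flip exactly one uniformly chosen locus in every member.

    Each output member is at genetic distance exactly 1 from its pre-image;
    loci are chosen independently per member.
    """
    return Population(_mutate(population.array, rng))


def replicate_population(
    population: Population,
    rng: np.random.Generator,
    expanded_size: int = 100,
) -> Population:
    """Expand by fitness-weighted sampling with replacement.

    Each member's expected offspring share is proportional to its fitness
    index; offspring are exact copies (no mutation during replication).
    When all members have fitness 0, sampling is uniform.
    """
    return Population(_replicate(population.array, rng, expanded_size))


def select_population(
    population: Population,
    rng: np.random.Generator,
    selected_size: int = 10,
) -> Population:
    """Bottleneck via binary tournaments.

    Each of ``selected_size`` survivors is the fitter of a pair drawn
    independently with replacement from the population (a member may be
    paired with itself); ties are broken uniformly at random.
    """
    return Population(_select(population.array, rng, selected_size))


def run_to_target(
    seed: GenotypeLike,
    target: GenotypeLike,
    config: Optional[SimulationConfig] = None,
    record_trajectory: bool = False,
) -> RunResult:
    """Run cycles from a homogeneous seed population until the target appears.

    Parameters
    ----------
    seed, target : Genotype or '0'/'1' string
        Starting genotype (all members initially identical) and the genotype
        whose appearance among the selected members stops the run.
    config : SimulationConfig, optional
        Population sizes, cycle cap and RNG seed; defaults model 12 loci
        with a 10 -> 100 -> 10 cycle.
    record_trajectory : bool
        When True, the result carries one :class:`TrajectoryPoint` per
        completed cycle (best and mean fitness of the selected members).

    Returns
    -------
    RunResult
        ``cycles`` is 0 when seed == target; otherwise the number of
        completed cycles at first detection of the target after selection,
        or ``max_cycles`` with ``terminated=False`` if the cap was hit.
    """
    config = config or SimulationConfig()
    seed_g = as_genotype(seed)
    target_g = as_genotype(target)
    if len(seed_g) != len(target_g):
        raise ValueError(
            f"seed and target lengths differ ({len(seed_g)} vs {len(target_g)})"
        )
    if len(seed_g) != config.locus_count:
        raise ValueError(
            f"genotype length {len(seed_g)} does not match config.locus_count "
            f"{config.locus_count}"
        )

    if seed_g == target_g:
        return RunResult(cycles=0, terminated=True, trajectory=() if record_trajectory else None)

    rng = np.random.default_rng(config.rng_seed)
    arr = np.tile(seed_g.to_array(), (config.seed_population_size, 1))
    target_row = target_g.to_array()
    trajectory = [] if record_trajectory else None

    for cycle in range(1, config.max_cycles + 1):
        arr = _mutate(arr, rng)
        arr = _replicate(arr, rng, config.expanded_population_size)
        arr = _select(arr, rng, config.seed_population_size)
        if record_trajectory:
            fit = arr.sum(axis=1)
            trajectory.append(
                TrajectoryPoint(cycle, int(fit.max()), float(fit.mean()))
            )
        if (arr == target_row).all(axis=1).any():
            return RunResult(
                cycles=cycle,
                terminated=True,
                trajectory=tuple(trajectory) if record_trajectory else None,
            )

    return RunResult(
        cycles=config.max_cycles,
        terminated=False,
        trajectory=tuple(trajectory) if record_trajectory else None,
    )
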