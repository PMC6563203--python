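"""Core domain types: diallelic genotypes, populations, configuration, results.

A genotype is an ordered string of L diallelic loci, each in state 0 or 1.
State 1 at a locus contributes positively to fitness in the (fixed) modeled
environment, so the fitness index of a genotype is simply its count of 1s.
Genetic distance between two genotypes is the Hamming distance in loci;
mutational distance is the number of mutation-replication-selection cycles
the simulator needs to turn a population seeded with one genotype into a
population containing the other (see :mod:`mevolve.engine`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "Genotype",
    "GenotypeLike",
    "Population",
    "SimulationConfig",
    "RunResult",
    "TrajectoryPoint",
    "as_genotype",
    "fitness_index",
    "genetic_distance",
]


@dataclass(frozen=True)
class Genotype:
    """An immutable string of L diallelic loci.

    The canonical text form is a '0'/'1' string whose leftmost character is
    locus 1, e.g. ``"111111111111"`` for the 12-locus all-ones genotype.
    """

    alleles: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) == 0:
            raise ValueError("a genotype must have at least one locus")
        if any(a not in (0, 1) for a in self.alleles):
            raise ValueError("alleles must be 0 or 1")

    @classmethod
    def from_string(cls, text: str) -> "Genotype":
        """Parse a '0'/'1' string (leftmost character = locus 1)."""
        if not text or any(c not in "01" for c in text):
            raise ValueError(
                f"genotype string must be a non-empty run of '0'/'1' characters, got {text!r}"
            )
        return cls(tuple(int(c) for c in text))

    @classmethod
    def from_array(cls, array: Sequence[int]) -> "Genotype":
        return cls(tuple(int(a) for a in array))

    def to_array(self) -> np.ndarray:
        return np.asarray(self.alleles, dtype=np.uint8)

    def complement(self) -> "Genotype":
        """The genotype with every allele flipped."""
        return Genotype(tuple(1 - a for a in self.alleles))

    @property
    def locus_count(self) -> int:
        return len(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)

    def __str__(self) -> str:
        return "".join(str(a) for a in self.alleles)


GenotypeLike = Union[Genotype, str, Sequence[int]]


def as_genotype(value: GenotypeLike) -> Genotype:
    """Coerce a genotype, '0'/'1' string, or 0/1 sequence to :class:`Genotype`."""
    if isinstance(value, Genotype):
        return value
    if isinstance(value, str):
        return Genotype.from_string(value)
    return Genotype.from_array(value)


def fitness_index(genotype: GenotypeLike) -> int:
    """Number of loci in state 1 — the genotype's fitness index.

    Each positive allele contributes one unit of fitness in the fixed
    modeled environment, so fitness ranges from 0 to L.
    """
    return sum(as_genotype(genotype).alleles)


def genetic_distance(a: GenotypeLike, b: GenotypeLike) -> int:
    """Hamming distance in loci between two genotypes of equal length."""
    ga, gb = as_genotype(a), as_genotype(b)
    if len(ga) != len(gb):
        raise ValueError(
            f"genotype lengths differ ({len(ga)} vs {len(gb)}); "
            "genetic distance is defined only for equal locus counts"
        )
    return sum(x != y for x, y in zip(ga.alleles, gb.alleles))


@dataclass(frozen=True)
class SimulationConfig:
    """All run parameters for the mutation-replication-selection cycle.

    Defaults model a 12-locus genome with a seed population of 10 that is
    expanded to 100 by fitness-weighted replication each cycle and bottlenecked
    back to 10 by binary tournaments.

    Parameters
    ----------
    locus_count : int
        Number of diallelic loci L.
    seed_population_size : int
        Population size after seeding and after each selection bottleneck.
    expanded_population_size : int
        Population size after replication; must be >= seed size.
    max_cycles : int
        Safety cap on cycles; runs hitting the cap are reported as censored
        (``terminated=False``) rather than raising.
    rng_seed : int or None
        Seed for the run's random stream; ``None`` draws entropy from the OS.
    """

    locus_count: int = 12
    seed_population_size: int = 10
    expanded_population_size: int = 100
    max_cycles: int = 100_000
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.locus_count < 1:
            raise ValueError("locus_count must be positive")
        if self.seed_population_size < 1:
            raise ValueError("seed_population_size must be positive")
        if self.expanded_population_size < self.seed_population_size:
            raise ValueError(
                "expanded_population_size must be >= seed_population_size"
            )
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


class Population:
    """A multiset of genotypes of equal locus count, stored as a 2-D 0/1 array."""

    __slots__ = ("_array",)

    def __init__(self, array: np.ndarray):
        arr = np.asarray(array, dtype=np.uint8)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("population array must be 2-D with at least one member")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("population entries must be 0 or 1")
        self._array = arr
        self._array.setflags(write=False)

    @classmethod
    def homogeneous(cls, genotype: GenotypeLike, size: int) -> "Population":
        """A population of ``size`` identical copies of ``genotype``."""
        g = as_genotype(genotype)
        return cls(np.tile(g.to_array(), (size, 1)))

    @classmethod
    def from_genotypes(cls, genotypes: Iterable[GenotypeLike]) -> "Population":
        rows = [as_genotype(g).to_array() for g in genotypes]
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise ValueError("all members must share the same locus count")
        return cls(np.stack(rows))

    @property
    def array(self) -> np.ndarray:
        """Read-only (size, L) array view of the members."""
        return self._array

    @property
    def size(self) -> int:
        return self._array.shape[0]

    @property
    def locus_count(self) -> int:
        return self._array.shape[1]

    def fitness_indices(self) -> np.ndarray:
        """Fitness index (count of 1s) of every member."""
        return self._array.sum(axis=1).astype(np.int64)

    def genotypes(self) -> list:
        return [Genotype.from_array(row) for row in self._array]

    def contains(self, genotype: GenotypeLike) -> bool:
        g = as_genotype(genotype)
        if len(g) != self.locus_count:
            return False
        return bool((self._array == g.to_array()).all(axis=1).any())

    def __len__(self) -> int:
        return self.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Population):
            return NotImplemented
        return self._array.shape == other._array.shape and bool(
            (self._array == other._array).all()
        )

    def __repr__(self) -> str:
        return f"Population(size={self.size}, locus_count={self.locus_count})"


class TrajectoryPoint(NamedTuple):
    """Per-cycle record of the selected population's fitness state."""

    cycle: int
    best_fitness: int
    mean_fitness: float


@dataclass(frozen=True)
class RunResult:
    """Outcome of one simulation run.

    ``cycles`` is the mutational distance: the number of completed
    mutation-replication-selection cycles at first detection of the target
    among the selected members (0 when the seed equals the target).
    ``terminated`` is False when the ``max_cycles`` cap was hit instead;
    in that case ``cycles == max_cycles``.
    """

    cycles: int
    terminated: bool
    trajectory: Optional[Tuple[TrajectoryPoint, ...]] = field(default=None)

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be non-negative")
        if self.trajectory is not None and len(self.trajectory) != self.cycles:
            raise ValueError("trajectory length must equal the number of cycles run")
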