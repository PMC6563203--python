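"""Distance sweeps and position-invariance checks.

The central experiment measures how mutational distance (cycles needed to
reach a target) scales with genetic distance (Hamming distance between seed
and target). For each requested distance d, seeds with exactly d zero
alleles are run against the all-ones target for a number of replicates, and
the per-distance mean, standard error, and range of cycle counts are
tabulated. Because every locus contributes identically to fitness, the
model is exchangeable in locus order; ``position_invariance_test`` verifies
empirically that permuting the zero positions of a seed leaves the cycle
distribution unchanged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import Genotype, GenotypeLike, SimulationConfig, as_genotype
from .engine import run_to_target

__all__ = [
    "enumerate_seeds",
    "run_sweep",
    "SweepResult",
    "position_invariance_test",
    "InvarianceReport",
]

SWEEP_COLUMNS = [
    "genetic_distance",
    "n_runs",
    "mean_cycles",
    "se_cycles",
    "min_cycles",
    "max_cycles_observed",
    "censored",
]

RUN_COLUMNS = ["genetic_distance", "seed_string", "replicate", "cycles", "terminated"]


def enumerate_seeds(
    distance: int,
    config: Optional[SimulationConfig] = None,
    mode: str = "all",
    sample_size: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> List[Genotype]:
    """Seed genotypes at a given genetic distance from the all-ones target.

    A seed at distance d is a string with exactly d zero alleles.

    Parameters
    ----------
    distance : int
        Number of zero alleles, 0 <= distance <= L.
    mode : {"all", "representative", "sample"}
        ``all`` returns every C(L, d) such string; ``representative``
        returns the single string with its zeros at the leftmost positions;
        ``sample`` returns ``sample_size`` distinct strings chosen uniformly.
    """
    config = config or SimulationConfig()
    L = config.locus_count
    if not 0 <= distance <= L:
        raise ValueError(f"distance must be in [0, {L}], got {distance}")

    if mode == "representative":
        return [Genotype(tuple([0] * distance + [1] * (L - distance)))]
    if mode == "all":
        seeds = []
        for zero_positions in itertools.combinations(range(L), distance):
            alleles = [1] * L
            for p in zero_positions:
                alleles[p] = 0
            seeds.append(Genotype(tuple(alleles)))
        return seeds
    if mode == "sample":
        total = math.comb(L, distance)
        if sample_size > total:
            raise ValueError(
                f"requested {sample_size} distinct seeds but only {total} exist"
            )
        rng = rng or np.random.default_rng()
        chosen: set = set()
        while len(chosen) < sample_size:
            zeros = tuple(sorted(rng.choice(L, size=distance, replace=False).tolist()))
            chosen.add(zeros)
        seeds = []
        for zero_positions in sorted(chosen):
            alleles = [1] * L
            for p in zero_positions:
                alleles[p] = 0
            seeds.append(Genotype(tuple(alleles)))
        return seeds
    raise ValueError(f"unknown mode {mode!r}; expected all, representative, or sample")


@dataclass(frozen=True)
class SweepResult:
    """Summary table and raw per-run records of a distance sweep.

    ``table`` has one row per genetic distance with mean/SE/min/max of the
    completed runs' cycle counts; ``censored`` counts runs that hit the
    cycle cap (those are excluded from the summary statistics).
    ``runs`` holds every individual run.
    """

    table: pd.DataFrame
    runs: pd.DataFrame
    target: str


def _summarize(distance: int, cycles: np.ndarray, censored: int) -> dict:
    n = len(cycles)
    if n == 0:
        return dict(
            genetic_distance=distance,
            n_runs=0,
            mean_cycles=np.nan,
            se_cycles=np.nan,
            min_cycles=np.nan,
            max_cycles_observed=np.nan,
            censored=censored,
        )
    se = float(cycles.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return dict(
        genetic_distance=distance,
        n_runs=n,
        mean_cycles=float(cycles.mean()),
        se_cycles=se,
        min_cycles=int(cycles.min()),
        max_cycles_observed=int(cycles.max()),
        censored=censored,
    )


def run_sweep(
    distances: Sequence[int],
    replicates_per_seed: int = 5,
    config: Optional[SimulationConfig] = None,
    mode: str = "representative",
    sample_size: int = 1,
    target: Optional[GenotypeLike] = None,
) -> SweepResult:
    """Run the mutational-distance sweep over a set of genetic distances.

    For each distance, every enumerated seed is run ``replicates_per_seed``
    times against the target (default all-ones). Replicate r of the sweep
    uses RNG seed ``config.rng_seed + r`` counted over all runs, so the
    whole sweep is reproducible from a single seed.
    """
    if replicates_per_seed < 1:
        raise ValueError("replicates_per_seed must be >= 1")
    config = config or SimulationConfig()
    L = config.locus_count
    target_g = (
        as_genotype(target) if target is not None else Genotype(tuple([1] * L))
    )
    if len(target_g) != L:
        raise ValueError("target length must equal config.locus_count")

    base_seed = config.rng_seed
    if base_seed is None:
        base_seed = int(np.random.SeedSequence().entropy % (2**31))

    seed_rng = np.random.default_rng(base_seed)
    run_records = []
    rows = []
    run_index = 0
    for distance in sorted(set(int(d) for d in distances)):
        seeds = enumerate_seeds(distance, config, mode=mode, sample_size=sample_size, rng=seed_rng)
        completed = []
        censored = 0
        for seed in seeds:
            for rep in range(replicates_per_seed):
                run_cfg = replace(config, rng_seed=base_seed + run_index)
                run_index += 1
                result = run_to_target(seed, target_g, run_cfg)
                run_records.append(
                    dict(
                        genetic_distance=distance,
                        seed_string=str(seed),
                        replicate=rep,
                        cycles=result.cycles,
                        terminated=result.terminated,
                    )
                )
                if result.terminated:
                    completed.append(result.cycles)
                else:
                    censored += 1
        rows.append(_summarize(distance, np.asarray(completed, dtype=np.int64), censored))

    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    runs = pd.DataFrame(run_records, columns=RUN_COLUMNS)
    return SweepResult(table=table, runs=runs, target=str(target_g))


@dataclass(frozen=True)
class InvarianceReport:
    """Outcome of the locus-order (position) invariance check.

    ``per_seed`` holds mean/SE per seed string; ``pairwise`` the two-sided
    Mann-Whitney U comparison for every seed pair; ``invariant`` is True
    when no pairwise comparison is significant at ``alpha``.
    """

    distance: int
    per_seed: pd.DataFrame
    pairwise: pd.DataFrame
    invariant: bool
    alpha: float
    note: str = ""


def position_invariance_test(
    distance: int,
    n_permutations: int = 5,
    replicates: int = 30,
    config: Optional[SimulationConfig] = None,
    alpha: float = 0.05,
    seeds: Optional[Sequence[GenotypeLike]] = None,
) -> InvarianceReport:
    """Check that permuting the zero positions of the seed leaves cycle counts alike.

    Runs ``replicates`` runs for each of ``n_permutations`` distinct seed
    strings with the same number of zero alleles (or for an explicit list of
    ``seeds``) and compares the cycle-count samples pairwise with a
    two-sided Mann-Whitney U test.
    """
    config = config or SimulationConfig()
    L = config.locus_count
    if not 1 <= distance <= L - 1:
        raise ValueError(f"distance must be in [1, {L - 1}], got {distance}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    base_seed = config.rng_seed
    if base_seed is None:
        base_seed = int(np.random.SeedSequence().entropy % (2**31))

    note = ""
    if seeds is not None:
        seed_list = [as_genotype(s) for s in seeds]
        for s in seed_list:
            if sum(1 for a in s.alleles if a == 0) != distance:
                raise ValueError(f"seed {s} does not have {distance} zero alleles")
    else:
        available = math.comb(L, distance)
        k = min(n_permutations, available)
        if k < n_permutations:
            note = (
                f"only {available} distinct seeds exist at distance {distance}; "
                f"ran all of them instead of the requested {n_permutations}"
            )
        picker = np.random.default_rng(base_seed)
        if k == available:
            seed_list = enumerate_seeds(distance, config, mode="all")
        else:
            seed_list = enumerate_seeds(
                distance, config, mode="sample", sample_size=k, rng=picker
            )

    samples = {}
    run_index = 0
    for seed in seed_list:
        cycles = []
        for _ in range(replicates):
            run_cfg = replace(config, rng_seed=base_seed + 1 + run_index)
            run_index += 1
            result = run_to_target(seed, Genotype(tuple([1] * L)), run_cfg)
            if result.terminated:
                cycles.append(result.cycles)
        samples[str(seed)] = np.asarray(cycles, dtype=np.int64)

    per_seed = pd.DataFrame(
        [
            dict(
                seed_string=s,
                n_runs=len(c),
                mean_cycles=float(c.mean()) if len(c) else np.nan,
                se_cycles=float(c.std(ddof=1) / np.sqrt(len(c))) if len(c) > 1 else 0.0,
            )
            for s, c in samples.items()
        ]
    )

    pair_rows = []
    invariant = True
    for (sa, ca), (sb, cb) in itertools.combinations(samples.items(), 2):
        if len(ca) == 0 or len(cb) == 0:
            continue
        stat, p = stats.mannwhitneyu(ca, cb, alternative="two-sided")
        significant = bool(p < alpha)
        if significant:
            invariant = False
        pair_rows.append(
            dict(seed_a=sa, seed_b=sb, u_statistic=float(stat), p_value=float(p), significant=significant)
        )
    pairwise = pd.DataFrame(
        pair_rows, columns=["seed_a", "seed_b", "u_statistic", "p_value", "significant"]
    )

    return InvarianceReport(
        distance=distance,
        per_seed=per_seed,
        pairwise=pairwise,
        invariant=invariant,
        alpha=alpha,
        note=note,
    )
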