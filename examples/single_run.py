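"""Run one mutation-replication-selection simulation and inspect its trajectory.

A homogeneous population of ten copies of the seed genotype evolves through
cycles of one-flip mutation, fitness-weighted expansion to 100, and
tournament bottleneck back to 10, until the all-ones target appears among
the ten selected members. The printed cycle count is the mutational
distance for this run; the trajectory shows the selected population's best
and mean fitness climbing toward 12.
"""

from mevolve import SimulationConfig, run_to_target

seed = "000000111111"  # genetic distance 6 from the target
target = "111111111111"

result = run_to_target(seed, target, SimulationConfig(rng_seed=7), record_trajectory=True)

print(f"seed={seed} target={target}")
print(f"mutational distance: {result.cycles} cycles (terminated={result.terminated})")
print("cycle  best_fitness  mean_fitness")
for point in result.trajectory[:5]:
    print(f"{point.cycle:>5}  {point.best_fitness:>12}  {point.mean_fitness:>12.1f}")
print("  ...")
for point in result.trajectory[-2:]:
    print(f"{point.cycle:>5}  {point.best_fitness:>12}  {point.mean_fitness:>12.1f}")
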