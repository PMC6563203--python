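"""Independent straight-line reimplementation of the simulation cycle.

Deliberately written without numpy and without reusing any package code:
plain Python lists and the stdlib ``random`` module. It serves as a
statistical oracle — the cycle-count distribution of the main engine must
match this one, even though the two consume randomness differently.
"""

import random


def naive_run(seed: str, target: str, n_small: int = 10, n_large: int = 100,
              max_cycles: int = 100_000, rng: random.Random = None):
    """Return (cycles, terminated) for one run of the naive cycle."""
    rng = rng if rng is not None else random.Random()
    L = len(seed)
    assert len(target) == L
    if seed == target:
        return 0, True
    population = [list(map(int, seed)) for _ in range(n_small)]
    target_list = list(map(int, target))
    for cycle in range(1, max_cycles + 1):
        # mutation: one random flip per string
        for member in population:
            pos = rng.randrange(L)
            member[pos] = 1 - member[pos]
        # replication: fitness-weighted copies up to n_large
        weights = [sum(member) for member in population]
        if sum(weights) == 0:
            weights = [1] * n_small
        expanded = [population[i][:] for i in
                    rng.choices(range(n_small), weights=weights, k=n_large)]
        # selection: binary tournaments with replacement
        survivors = []
        for _ in range(n_small):
            i = rng.randrange(n_large)
            j = rng.randrange(n_large)
            fi, fj = sum(expanded[i]), sum(expanded[j])
            if fi > fj:
                winner = i
            elif fj > fi:
                winner = j
            else:
                winner = i if rng.random() < 0.5 else j
            survivors.append(expanded[winner][:])
        population = survivors
        if any(member == target_list for member in population):
            return cycle, True
    return max_cycles, False
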