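# Methods

## The mutation-replication-selection cycle

The simulator is a forward-time haploid model on binary genotypes of L
diallelic loci. Fitness is additive and environment-independent: the
fitness index of a genotype is its count of 1 alleles, so the landscape is
a single smooth peak at the all-ones string. Each cycle applies, in order:

- **Mutation**: exactly one locus, chosen uniformly and independently per
  member, is flipped in every member. The per-genome mutation rate is
  therefore fixed at 1 per cycle — strong mutation pressure by design.
- **Replication**: the population of n members expands to N by sampling
  parents with replacement, each weighted by fitness index. This is the
  simplest scheme making expected offspring counts proportional to fitness;
  offspring are exact copies. If the total fitness is zero (only possible
  for an all-zeros population), sampling falls back to uniform.
- **Selection**: a bottleneck back to n by binary tournaments. Pairs are
  drawn with replacement, and the two pair members independently, so a
  member can be compared with itself (returning itself); ties are broken
  uniformly at random. With-replacement drawing is the simplest
  reproducible reading of "random selections of pairs" and avoids order
  bias.

Termination is checked after selection only: the run stops when the target
genotype is among the n selected members, and reports the number of
completed cycles (the mutational distance). A target appearing transiently
among the N expanded members but not surviving the bottleneck does not
stop the run. A seed equal to its target reports 0 cycles. Because a
low-fitness target is actively removed by selection, the process is not
guaranteed to halt; a configurable cap (default 100 000 cycles) converts
such runs into censored results (`terminated=False`) rather than errors.

Defaults: L = 12, n = 10, N = 100. These are the study conditions the
package models throughout; all are configurable.

### Randomness and reproducibility

Each run consumes a single numpy `default_rng` stream seeded from its
configuration. A sweep with base seed s gives run r the seed s + r, so
whole experiments are bit-reproducible from one integer while replicates
remain independent. CLI invocations record the resolved configuration,
seed, and SHA-256 digests of all outputs in a JSON manifest.

## Behavior of the cycle-count statistic

Two regimes shape a run. First a short adaptive climb: tournament selection
plus fitness-weighted replication push the population to the top of the
landscape within a few cycles (roughly proportional to the starting genetic
distance). Then a stochastic wait: mutation keeps knocking members off the
summit (every member flips one locus every cycle), so the exact target
string appears among the ten survivors only when a fitness-11 member flips
its single remaining 0 and the resulting all-ones string survives the
bottleneck. The waiting time dominates the total and is identical in law
for every seed, which is why mean cycle counts rise with genetic distance
(the climb lengthens) but only by a few cycles per unit distance, and why
the dispersion is large (the wait is approximately geometric). Under the
default conditions the measured means run from about 7 cycles at distance 1
to about 23 at distance 8 (see `examples/distance_sweep.py` and
`scripts/acceptance.py` for the computed values at any seed).

Strict monotonicity of the mean in distance is a small effect (about 2
cycles per unit against a per-run standard deviation near 14), so the test
asserting it uses 800 replicates per distance; smaller designs have no
power against noise. Because every locus enters fitness identically, the
model is exactly exchangeable in locus order; permuting the zero positions
of a seed cannot change the cycle-count distribution, and the
position-invariance report checks this empirically with two-sided
Mann-Whitney comparisons.

The engine is validated against an independently coded straight-line
reimplementation of the cycle (pure Python, stdlib `random`, no shared
code); the two implementations' cycle-count means are required to agree
within two combined standard errors.

## Genotype networks

Nodes are genotypes passing a viability rule — fitness index at or above a
threshold, or explicit membership in a conditionally-viable set — and edges
join genotypes at Hamming distance 1. Construction is by exhaustive
enumeration of all 2^L strings, guarded at L ≤ 20 (the conceptual networks
of interest are small; sampling-based construction is out of scope).
"Module" is operationalized as a connected component: the informal notion
of an edge-dense grouping is not algorithmically specified, and components
are the reproducible choice. A module's boundary nodes are those adjacent,
in the full hypercube, to at least one genotype outside the network.
Degree histograms are summarized descriptively (mean, variance,
variance/mean ratio, and a chi-square statistic against a Poisson with the
matched mean, tail mass pooled); Poisson-likeness is a qualitative
expectation for thresholded random landscapes, not a pass/fail criterion,
so no significance decision is attached. Joining networks through
conditionally viable bridge nodes recomputes all distance-1 edges over the
union and reports whether previously separate components merged.

## Pairwise-identity histograms

Identity is computed either over aligned columns (equal-length sequences,
matches / length) or after a global alignment (Biopython PairwiseAligner,
EMBOSS-like scoring: match +5, mismatch −4, gap open −10, extend −0.5) with
terminal-gap columns excluded and internal gap columns counted as compared
mismatches. The method used is recorded in the output metadata; no single
standard protocol exists for this display, which is why both are offered.
Identities are binned into half-open bins (last bin closed) so the total
count is exactly C(n, 2). Peaks are local maxima of the 3-bin
moving-average of the total counts; valleys are the minima between
consecutive peaks. The smoothing window is the smallest that prevents
single-bin jitter from splitting one divergence band into two peaks.

### The synthetic fixture and what it does and does not emulate

The generator draws a random root sequence; cluster 1's ancestor is the
root and each further cluster's ancestor mutates the root at the
between-cluster rate; members mutate their ancestor at the within-cluster
rate. A substitution replaces a base with one of the three other bases, so
per-lineage divergence equals the nominal rate. Exact expectations follow
by per-site enumeration: two members of one cluster match at a site with
probability (1−w)² + w²/3, and members of different clusters (two-cluster
case) with probability (1−b)[(1−w)² + w²/3] + b[2w(1−w)/3 + 2w²/9]. At the
default w = 0.02, b = 0.20 the designed bands are ≈96.1% within and ≈77.1%
between — well separated, so the two-peak recovery test is stable at fixed
seed. The fixture emulates only the clustered-divergence geometry of real
taxon sets: sites are i.i.d., there is no rate heterogeneity, indel,
recombination, selection, or phylogenetic structure within clusters.
Passing the recovery test shows the histogram and peak detection are
correct, not that real sequence collections will show clean peaks.

## Numerical and design choices

- Standard errors use the n−1 sample standard deviation; censored runs are
  excluded from means/SEs and reported as a separate count.
- Sweeps default to one representative seed per distance (zeros leftmost);
  locus exchangeability makes per-seed enumeration redundant, but `all`
  and `sample:k` modes are available.
- Default sweep target is the all-ones string; arbitrary targets are
  accepted everywhere.
- Genotypes are ordered 0/1 vectors; the text form is a '0'/'1' string
  with locus 1 leftmost.
- Problem sizes in the committed tests (replicate counts, sequence
  lengths) were chosen as the smallest giving the relevant statistic
  adequate power at the documented effect sizes.

## Known limitations

- The model has a single smooth additive peak: no epistasis, neutrality,
  recombination, hypermutation, or environmental change. Extensions that
  close or open mutational paths are not modeled.
- Mutational distance is defined by first appearance of an exact target
  string in a 10-member sample; it is a hitting time, not a substitution
  count, and its absolute scale is set by the strong-selection/strong-
  mutation regime of the defaults. Cycle counts in the tens, not
  thousands, are intrinsic to these conventions: fitness-proportional
  replication plus binary tournaments fix the target's ascent after a few
  cycles, and no consistent variant of the stated cycle (weaker selection,
  stricter termination, random bottleneck) that we examined yields
  hitting times orders of magnitude larger while preserving the strong
  distance dependence. See the repository's acceptance script for the
  measured increments.
- The network module enumerates exhaustively and is memory-bound above
  L ≈ 20; identity histograms are all-vs-all and quadratic in the number
  of sequences.
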