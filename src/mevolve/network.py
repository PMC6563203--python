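"""Genotype networks on the diallelic hypercube.

Nodes are viable genotypes — genotypes whose fitness index meets a
threshold, interpreted as able to produce multiple copies of themselves
(basic reproduction number above one) in the modeled environment. Edges
join genotypes at genetic distance 1, i.e. single-locus changes. Connected
components ("modules") of such a network correspond to strains: clouds of
sequences reachable from one another through viable single-step mutants.
Separate modules can fuse into a supermodule (a species-level grouping)
when conditionally viable genotypes — viable only under particular
conditions — bridge them.

Networks are represented as :class:`networkx.Graph` objects whose nodes are
'0'/'1' genotype strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, FrozenSet, Iterable, List, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ViabilityRule",
    "build_network",
    "degree_distribution",
    "DegreeDistribution",
    "module_summary",
    "ModuleStats",
    "connect_supermodule",
    "SupermoduleResult",
    "MAX_ENUMERABLE_LOCI",
]

MAX_ENUMERABLE_LOCI = 20


@dataclass(frozen=True)
class ViabilityRule:
    """Viability predicate: fitness index >= threshold, or explicit membership.

    ``conditional_set`` lists genotypes treated as viable regardless of the
    threshold (e.g. conditionally viable bridging sequences).
    """

    threshold: int
    conditional_set: FrozenSet[str] = field(default_factory=frozenset)

    def __call__(self, genotype: str) -> bool:
        return genotype.count("1") >= self.threshold or genotype in self.conditional_set


def _all_genotypes(L: int) -> Iterable[str]:
    for i in range(2**L):
        yield format(i, f"0{L}b")


def _neighbors(genotype: str) -> Iterable[str]:
    for i, c in enumerate(genotype):
        yield genotype[:i] + ("1" if c == "0" else "0") + genotype[i + 1 :]


def _graph_from_nodes(nodes: Sequence[str]) -> nx.Graph:
    node_set = set(nodes)
    graph = nx.Graph()
    graph.add_nodes_from(node_set)
    for node in node_set:
        for nb in _neighbors(node):
            if nb in node_set:
                graph.add_edge(node, nb)
    return graph


def build_network(
    L: int,
    rule: Union[ViabilityRule, Callable[[str], bool]],
) -> nx.Graph:
    """Enumerate all 2^L genotypes, keep the viable ones, connect distance-1 pairs.

    ``rule`` is a :class:`ViabilityRule` or any predicate on genotype strings.
    Enumeration is exhaustive, so L is capped at ``MAX_ENUMERABLE_LOCI``.
    """
    if L < 1:
        raise ValueError("L must be positive")
    if L > MAX_ENUMERABLE_LOCI:
        raise ValueError(
            f"L={L} exceeds the exhaustive-enumeration guard ({MAX_ENUMERABLE_LOCI}); "
            "build the network on a sampled node set instead"
        )
    nodes = [g for g in _all_genotypes(L) if rule(g)]
    graph = _graph_from_nodes(nodes)
    graph.graph["locus_count"] = L
    return graph


@dataclass(frozen=True)
class DegreeDistribution:
    """Degree histogram with descriptive Poisson-likeness statistics.

    ``counts`` maps degree k to the number of nodes with that degree.
    ``chi_square`` compares the observed histogram against a Poisson with
    the same mean (tail mass pooled into the last class); it is reported
    descriptively, not as a pass/fail test.
    """

    counts: dict
    mean_degree: float
    variance: float
    variance_mean_ratio: float
    chi_square: Optional[float]
    chi_square_dof: Optional[int]
    fit_defined: bool


def degree_distribution(net: nx.Graph) -> DegreeDistribution:
    """Histogram of node degrees plus mean and Poisson-comparison statistics."""
    degrees = np.array([d for _, d in net.degree()], dtype=np.int64)
    if degrees.size == 0:
        return DegreeDistribution(
            counts={},
            mean_degree=float("nan"),
            variance=float("nan"),
            variance_mean_ratio=float("nan"),
            chi_square=None,
            chi_square_dof=None,
            fit_defined=False,
        )
    values, freq = np.unique(degrees, return_counts=True)
    counts = {int(v): int(f) for v, f in zip(values, freq)}
    mean = float(degrees.mean())
    var = float(degrees.var(ddof=0))
    ratio = var / mean if mean > 0 else float("nan")

    chi = None
    dof = None
    fit_defined = mean > 0
    if fit_defined:
        kmax = int(degrees.max())
        observed = np.zeros(kmax + 2)
        for k, f in counts.items():
            observed[k] = f
        pmf = stats.poisson.pmf(np.arange(kmax + 1), mean)
        expected = np.append(pmf, stats.poisson.sf(kmax, mean)) * degrees.size
        keep = expected > 0
        chi = float(((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum())
        dof = int(keep.sum() - 1)
    return DegreeDistribution(
        counts=counts,
        mean_degree=mean,
        variance=var,
        variance_mean_ratio=ratio,
        chi_square=chi,
        chi_square_dof=dof,
        fit_defined=fit_defined,
    )


@dataclass(frozen=True)
class ModuleStats:
    """Per-module (connected component) summary."""

    module_id: int
    n_nodes: int
    n_edges: int
    mean_degree: float
    boundary_nodes: int


def module_summary(net: nx.Graph) -> List[ModuleStats]:
    """Connected components with size, edge count, mean degree, boundary count.

    A boundary node has at least one hypercube neighbor (distance-1
    genotype) that is not itself in the network — it sits at the periphery
    of its module, adjacent to non-viable sequence space.
    """
    node_set = set(net.nodes)
    modules = []
    components = sorted(nx.connected_components(net), key=lambda c: (-len(c), min(c)))
    for module_id, component in enumerate(components):
        sub = net.subgraph(component)
        boundary = sum(
            1 for node in component if any(nb not in node_set for nb in _neighbors(node))
        )
        n_nodes = sub.number_of_nodes()
        n_edges = sub.number_of_edges()
        modules.append(
            ModuleStats(
                module_id=module_id,
                n_nodes=n_nodes,
                n_edges=n_edges,
                mean_degree=2.0 * n_edges / n_nodes,
                boundary_nodes=boundary,
            )
        )
    return modules


@dataclass(frozen=True)
class SupermoduleResult:
    """Result of joining networks through conditionally viable nodes."""

    network: nx.Graph
    components_before: int
    components_after: int
    merged: bool


def connect_supermodule(
    nets: Sequence[nx.Graph],
    conditional_nodes: Iterable[str],
) -> SupermoduleResult:
    """Union the node sets, add conditional nodes, recompute distance-1 edges.

    Conditionally viable genotypes can bridge otherwise separate modules;
    ``merged`` reports whether the total component count dropped below the
    sum of the input networks' component counts.
    """
    if not nets:
        raise ValueError("at least one network is required")
    conditional = set(conditional_nodes)
    lengths = {len(n) for net in nets for n in net.nodes} | {len(n) for n in conditional}
    if len(lengths) > 1:
        raise ValueError("all genotypes must share the same locus count")
    existing = set().union(*(set(net.nodes) for net in nets))
    overlap = conditional & existing
    if overlap:
        raise ValueError(
            f"conditional nodes must not already be viable: {sorted(overlap)[:5]}"
        )

    components_before = sum(nx.number_connected_components(net) for net in nets)
    merged_graph = _graph_from_nodes(sorted(existing | conditional))
    if lengths:
        merged_graph.graph["locus_count"] = next(iter(lengths))
    components_after = nx.number_connected_components(merged_graph)
    return SupermoduleResult(
        network=merged_graph,
        components_before=components_before,
        components_after=components_after,
        merged=components_after < components_before,
    )
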