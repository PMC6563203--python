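"""Genotype networks: viability thresholds, degree statistics, supermodules.

Viable genotypes (fitness index at or above a threshold) are nodes; single
locus changes are edges. At threshold 0 the network is the full hypercube
(every node has degree L); raising the threshold prunes it to a module of
high-fitness sequences. Two separate modules can merge into a supermodule
when a conditionally viable genotype bridges them.
"""

from mevolve import (
    ViabilityRule,
    build_network,
    connect_supermodule,
    degree_distribution,
    module_summary,
)

for threshold in (0, 8, 11):
    net = build_network(12, ViabilityRule(threshold))
    dist = degree_distribution(net)
    modules = module_summary(net)
    print(
        f"threshold {threshold:>2}: {net.number_of_nodes():>4} nodes, "
        f"{net.number_of_edges():>5} edges, mean degree {dist.mean_degree:.2f}, "
        f"variance/mean {dist.variance_mean_ratio:.2f}, "
        f"{len(modules)} module(s), {modules[0].boundary_nodes} boundary nodes"
    )

# two strains as isolated modules, merged through one conditionally viable node
strain_a = build_network(4, lambda g: g == "1111")
strain_b = build_network(4, lambda g: g == "1100")
merged = connect_supermodule([strain_a, strain_b], {"1110"})
print(
    f"\nsupermodule: {merged.components_before} modules -> "
    f"{merged.components_after} after adding the bridge node 1110 "
    f"(merged={merged.merged})"
)
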