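"""Extract trait modules from a node-weighted network by propagation.

Builds the trait-specific network (-log10 gene p-values as node weights),
diffuses the weights with a random walk with restart, thresholds the
asymmetric similarity matrix into a nested hierarchy of strongly
connected components, and selects the cut where the largest component is
most surprising relative to a permutation null.
"""

from mprsnet.network import build_weighted_network, largest_connected_component
from mprsnet.propagation import (
    build_scc_hierarchy,
    compute_similarity_matrix,
    select_cut_and_score,
)
from mprsnet.synthetic import SimulationConfig, generate_gene_scores, generate_network, _gene_names

cfg = SimulationConfig(seed=42)
edges, planted = generate_network(cfg)
scores = generate_gene_scores(_gene_names(cfg.n_genes), planted, cfg, side="L")

net = largest_connected_component(build_weighted_network(edges, scores))
print(f"trait network: {net.n_nodes} genes, {net.n_edges} interactions")

model = compute_similarity_matrix(net, beta=0.4)
hierarchy = build_scc_hierarchy(model)
print(f"hierarchy: {len(hierarchy.thresholds)} thresholds, "
      f"{len(hierarchy.partitions)} distinct partitions")

delta_star, modules = select_cut_and_score(hierarchy, net, beta=0.4, n_perm=99, seed=7)
print(f"selected cut delta* = {delta_star:.3f}")
for m in modules:
    overlap = len(set(m.genes) & set(planted["planted1"]))
    print(f"  {m.module_id}: {m.size} genes, permutation p = {m.perm_p:.3f}, "
          f"{overlap}/{len(planted['planted1'])} planted genes recovered")
# A small permutation p (floor 1/(n_perm+1) = 0.01 here) means no
# degree-matched reshuffling of the gene scores produced a comparably
# coherent hot region anywhere in the hierarchy.
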