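"""Reconstruct promoter-hub networks and test hub genes for enrichment.

Anchors are nodes (identity = exact coordinates), loops are PET-weighted
edges, clusters are connected components.  A hub of 34 promoters and 10
enhancers is planted and recovered; hub genes are then tested against a
toy gene-set collection with the hypergeometric test.
"""
from loophub import (
    HubSpec, SyntheticSpec, annotate_loops, build_graph, clusters,
    compare_cluster_sizes, derive_catalog, filter_loops,
    generate_annotations, generate_loops, hub_gene_enrichment,
)
from loophub.hubs import assign_genes_to_promoter_nodes

spec = SyntheticSpec(
    seed=0, hubs=(HubSpec(n_promoters=34, n_enhancers=10),),
    n_loops=43 + 60, n_decoys=0, unique_background_anchors=True,
)
ann = generate_annotations(spec)
truth = generate_loops(spec, ann)
catalog = derive_catalog(ann.genes, ann.repeats, ann.histone_peaks)
graph = build_graph(annotate_loops(filter_loops(truth.loops), catalog))
gene_lookup = assign_genes_to_promoter_nodes(graph, ann.genes)
stats = clusters(graph, gene_lookup)

top = stats[0]
print(f"{len(stats)} clusters; the largest connects "
      f"{top.n_promoters} promoters and {top.n_enhancers} enhancers "
      f"({top.n_nodes} nodes, total PET weight {top.total_pets})")
sizes_rest = [c.n_nodes for c in stats[1:]]
print(f"background components have {min(sizes_rest)}-{max(sizes_rest)} nodes")

# rank-sum comparison of cluster sizes between two synthetic conditions
other = [c.n_nodes for c in stats[1:]]
p = compare_cluster_sizes([top.n_nodes] + other[:10], other[10:30])
print(f"rank-sum p comparing two cluster-size groups: {p:.3g}")

# over-representation of hub genes in a toy gene-set collection
universe = [g.gene_id for g in ann.genes]
gene_sets = {
    "contains_hub_genes": top.genes[:20] + universe[:30],
    "random_set": universe[-50:],
}
for r in hub_gene_enrichment(top.genes, gene_sets, universe):
    flag = "*" if r.significant else " "
    print(f"{flag} {r.set_name:20s} overlap {r.overlap:2d}/{r.set_size:3d} "
          f"p = {r.p_value:.3g}  q = {r.q_value:.3g}")
print("\n* = enriched at q <= 0.05 (Benjamini-Hochberg).")
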