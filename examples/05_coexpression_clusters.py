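"""Coexpression network and Markov clustering of a synthetic atlas.

Averages libraries by (BioProject, tissue, breed, sex), filters weakly
expressed genes, thresholds the gene-to-gene Pearson matrix and clusters
the graph with MCL — then checks the planted modules were recovered.
"""

from sklearn.metrics import adjusted_rand_score

from coexatlas import (
    AtlasDesign,
    aggregate,
    build_graph,
    correlate,
    expression_filter,
    mcl,
    profiles,
    simulate_expression,
    threshold_scan,
)

design = AtlasDesign(n_genes=500, n_tissues=8, libraries_per_tissue=5,
                     corrupt_fraction=0.0, seed=3)
truth = simulate_expression(design)

atlas = aggregate(truth.true_tpm)
print(f"{truth.true_tpm.n_samples} libraries -> {atlas.n_samples} atlas samples")

filtered = expression_filter(atlas, min_tpm=10.0)
corr = correlate(filtered, axis="gene")
print(threshold_scan(corr, [0.5, 0.7, 0.9]).to_string(index=False))

graph = build_graph(corr, threshold=0.70)
clusters = mcl(graph, inflation=2.2)
print(f"r >= 0.70: {graph.n_nodes} nodes, {graph.n_edges} edges, "
      f"{len(clusters.clusters)} clusters "
      f"(sizes {[len(c) for c in clusters.clusters[:6]]} ...)")

labels = clusters.labels()
module = truth.module_membership
common = [g for g in module if g in labels]
ari = adjusted_rand_score([module[g] for g in common],
                          [labels[g] for g in common])
print(f"adjusted Rand index vs planted modules: {ari:.2f}")

for p in profiles(clusters, atlas, min_size=10)[:3]:
    tissue = atlas.samples.loc[p.top_samples[0], "tissue"]
    print(f"cluster {p.cluster_number} (n={p.size}): "
          f"highest mean expression in {tissue}")
# ARI 1.0 means each planted tissue module maps onto exactly one MCL
# cluster; each cluster's mean profile peaks in the tissue that drove it.
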