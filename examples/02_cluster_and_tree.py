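"""Subclonal reconstruction: read counts -> CCFs -> clusters -> clone tree.

Simulates a benchmark tumor, clusters its mutations across regions with the
Dirichlet-process sampler, applies the cluster-removal rules, builds the
clone tree under the pigeonhole and crossing constraints, and reports how
well the truth was recovered.
"""

import numpy as np

from clonalith.benchmark import benchmark_tumor
from clonalith.inference import cluster_variants, filter_clusters
from clonalith.phylo import build_tree, label_tree, to_newick, trunk_fraction

cfg, truth, segments, variants = benchmark_tumor(seed=7)
purity = dict(zip(truth.region_names, truth.purity))

clusters, ccfs = cluster_variants(variants, segments, purity, seed=7,
                                  n_iter=800, burn_in=400)
clusters, audit = filter_clusters(
    clusters, variants.variants.loc[clusters.mutation_index, "chrom"])

print(f"true clusters: {truth.n_clusters}; recovered: {clusters.n_clusters}")
print("estimated centroids (clusters x regions):")
print(np.round(clusters.centroids, 2))
print("true centroids:")
print(np.round(truth.cluster_ccf, 2))

tree = label_tree(build_tree(clusters))
counts = np.bincount(clusters.assignment, minlength=tree.n_clusters)
print("inferred parent vector:", tree.parent.tolist(),
      "| constraint violation:", round(tree.violation, 4))
print("labels:", tree.labels)
print("trunk fraction:", round(trunk_fraction(clusters, tree), 3),
      "(fraction of mutations carried by every tumor cell)")
print("newick:", to_newick(tree, counts))
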