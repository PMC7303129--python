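"""Methylation ITH and genomic-epigenomic congruence.

Pools pairwise distances over a small cohort of simulated tumors and
correlates methylation distances (Euclidean, top-5000 most variable probes)
with subclonal-SNV distances — congruent genomes and epigenomes give a
positive Spearman rho.
"""

import pandas as pd

from clonalith import SimConfig
from clonalith.metrics import (
    cluster_methylation, congruence_from_pairs, congruence_pairs,
    methylation_variability, presence_matrix, select_top_variable_probes,
)
from clonalith.simulate import simulate_methylation, simulate_reads, simulate_tree
import numpy as np

pairs = []
for t in range(8):
    cfg = SimConfig(n_regions=6, n_clusters=5, n_mutations=400, n_probes=8000,
                    meth_signal_fraction=0.6, seed=100 + t)
    rng = np.random.default_rng(100 + t)
    truth = simulate_tree(cfg, rng)
    variants = simulate_reads(truth, cfg, None, rng, include_normal=False)
    beta = simulate_methylation(truth, cfg, rng)
    presence = presence_matrix(variants)
    pairs.append(congruence_pairs(presence, truth.mutation_cluster == 0,
                                  beta, truth.region_names))

allp = pd.concat(pairs, ignore_index=True)
res = congruence_from_pairs(allp["snv_distance"], allp["beta_distance"])
print(f"congruence over {res.n_pairs} sample pairs from 8 tumors: "
      f"rho = {res.rho:.2f}, p = {res.p_value:.2g}")
print("(positive rho: pairs of regions that differ more in subclonal SNVs "
      "also differ more in methylation)")

# per-tumor methylation variability and tumor/normal separation
cfg = SimConfig(n_regions=5, n_probes=5000, seed=3)
rng = np.random.default_rng(3)
truth = simulate_tree(cfg, rng)
beta = simulate_methylation(truth, cfg, rng)
mv = methylation_variability(beta, truth.region_names)
print("median per-probe beta range by genomic context (top 3):")
print(mv.sort_values(ascending=False).head(3).round(3).to_string())
top = select_top_variable_probes(beta, fraction=0.01,
                                 tumor_samples=truth.region_names)
mc = cluster_methylation(beta, probes=top, normal_samples=["N01"])
print(f"tumor/normal separation score at k=2 (Ward, Euclidean): "
      f"{mc.separation_score}")
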