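"""Simulate a multi-region tumor with known ground truth.

Builds a 4-region tumor (60X coverage, ~70% truncal mutations, clonal
arm-level plus subclonal focal copy-number events) and prints the true
subclone tree and per-region cancer cell fractions (CCFs).
"""

import numpy as np

from clonalith import SimConfig, simulate_tumor

config = SimConfig(n_regions=4, n_clusters=5, n_mutations=600, seed=42)
bundle, truth = simulate_tumor(config, seed=42, tumor_id="example")

print(f"tumor {bundle.manifest.tumor_id}: "
      f"{len(bundle.manifest.tumor_samples)} tumor regions, "
      f"{bundle.variants.n_variants} somatic SNVs, "
      f"{len(bundle.svs)} SVs, {len(bundle.betas.probes)} methylation probes")
print("true parent vector:", truth.parent.tolist(),
      "(-1 marks the truncal clone)")
print("true cluster CCFs (clusters x regions):")
print(np.round(truth.cluster_ccf, 2))
print("per-region purity:", np.round(truth.purity, 2))
# Each row is a subclone; the root row is 1.0 everywhere (every tumor cell
# carries truncal mutations), children never exceed their parent, and
# sibling rows never sum above their parent (pigeonhole principle).
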