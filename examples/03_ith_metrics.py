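"""Intratumor-heterogeneity summaries for one simulated tumor.

Computes APITH (average pairwise ITH: the mean number of mutations private
to one sample of a pair), the clonal/subclonal genome fractions from joint
copy-number states across regions, the clonal-vs-subclonal SCNA size
comparison, and SV clonality by shared breakpoints.
"""

from clonalith import SimConfig, simulate_tumor
from clonalith.metrics import (
    apith, compare_scna_sizes, presence_matrix, scna_clonal_fraction,
    scna_events, sv_clonality,
)

bundle, truth = simulate_tumor(SimConfig(n_svs=20, seed=11), seed=11)
tumor_samples = bundle.manifest.tumor_samples

presence = presence_matrix(bundle.variants, samples=tumor_samples)
print(f"APITH = {apith(presence):.2f} mutations "
      f"(mean pairwise discordance over {len(tumor_samples)} regions)")

fr = scna_clonal_fraction(bundle.segments, tumor_samples)
print(f"genome fractions: clonal {fr['clonal_fraction']:.2%}, "
      f"subclonal {fr['subclonal_fraction']:.2%}, "
      f"unaltered {fr['unaltered_fraction']:.2%} (sums to 1 exactly)")

ev = scna_events(bundle.segments, tumor_samples)
clonal = ev.loc[ev.clonality == "clonal", "size"]
subclonal = ev.loc[ev.clonality == "subclonal", "size"]
stat, p = compare_scna_sizes(clonal, subclonal)
print(f"SCNA sizes: clonal median {clonal.median()/1e3:.0f} kb vs subclonal "
      f"{subclonal.median()/1e3:.0f} kb; one-sided rank-sum p = {p:.3g}")

sv = sv_clonality(bundle.svs, tumor_samples)
print(f"SVs: {sv['clonal_count']} clonal / {sv['subclonal_count']} subclonal; "
      f"shared fraction {sv['shared_fraction']:.2f} "
      f"(events with breakpoints in every region)")
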