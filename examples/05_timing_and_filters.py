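"""Copy-number gain timing and record-level filters.

Times a single-copy gain from the duplicated/non-duplicated clonal mutation
ratio, orders a driver mutation against the LOH of its segment, and runs the
indel / targeted-sequencing / driver-classification rule engines.
"""

from clonalith.filters import classify_driver, filter_indels, filter_targeted
from clonalith.phylo import order_mutation_vs_scna, time_gain

# A 2+1 gain: mutations that predate the gain were duplicated (multiplicity
# 2). 20 duplicated vs 220 single-copy clonal mutations:
res = time_gain(n1=220, n2=20, gain_type="2+1")
print(f"2+1 gain: N1={res.n1}, N2={res.n2} -> relative molecular time "
      f"t = {res.t:.3f} (early: few duplicated mutations)")

res = time_gain(n1=100, n2=50, gain_type="2+0")
print(f"CNLOH:    N1={res.n1}, N2={res.n2} -> t = {res.t:.3f}")

o = order_mutation_vs_scna(2, 2, 0, clonal=True)
print(f"clonal mutation at multiplicity 2 in a CNLOH segment: occurred "
      f"'{o.order_relation}' the LOH (it was duplicated by it)")

d = filter_indels(tumor_alt=4, tumor_depth=60, normal_alt=0, normal_depth=30)
print(f"indel consensus filter (alt 4/60 tumor, 0/30 normal): {d.verdict}")
d = filter_targeted(tumor_alt=7, tumor_depth=500)
print(f"targeted filter (7 supporting reads at 500X): {d.verdict} "
      f"({', '.join(d.failed_rules)})")
call = classify_driver("stop-gain", sift=0.01)
print(f"stop-gain with SIFT 0.01 in a driver gene: {call}")
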