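# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `clonalith`. Everything empirical stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
external runs.

## The allele-fraction model

All read-count reasoning goes through one equation. A mutation present on
`m` of the `CN` copies of its locus, carried by a fraction `φ` (CCF) of
tumor cells in a sample of purity `ρ`, has expected variant allele fraction

    VAF = m·φ·ρ / (ρ·CN + 2(1−ρ)).

The simulator draws alt counts Binomial(depth, VAF) with depth ~
Poisson(mean 60), emulating ~60X whole-genome coverage with its natural
dispersion. CCF estimation inverts the equation; the multiplicity call
rounds `VAF·(ρ·CN+2(1−ρ))/ρ` half-up (determinism) and clamps it to
`[1, major_CN]`. Estimated CCFs above 1.2 are clamped and flagged: values
mildly above 1 are expected from binomial noise at clonal mutations, values
far above 1 indicate an inconsistent copy-number or purity call.

Purity from VAF (used for copy-neutral samples) takes SNVs in diploid
heterozygous segments, finds the highest-VAF local maximum of a Gaussian
KDE, re-centres it with a few mean-shift steps (the raw KDE mode is biased
by depth heterogeneity and binomial skew), and returns `ρ = 2·mode` clamped
to [0.05, 1].

## Dirichlet-process clustering

Mutations of one tumor are clustered jointly across its regions with a
truncated stick-breaking DP mixture (truncation K=30) with binomial
emissions through the forward equation. Per sweep: cluster CCFs are
Gibbs-sampled on a per-sample grid (step 0.02, range [0, 1.2]); stick
weights from their Beta conditionals; the concentration α from its
Gamma(1,1) conditional; assignments from the categorical conditional.
Defaults: 2,000 sweeps, 1,000 burn-in. Mutations are pre-sorted by a
data-determined key before sampling, so results are invariant to the input
order (exchangeability) and fully determined by the seed.

Clusters are read off the *posterior mutation density*, not the chain
labels: each mutation's posterior-mean CCF vector is accumulated after
burn-in; for up to 3 regions the density is histogrammed on the 0.02 grid,
smoothed (Gaussian, σ = 1 cell) and its local maxima taken as candidate
clone positions (above 3 regions, modes of the rounded posterior-mean
vectors are used, merged greedily by mass within a 0.1 max-norm radius —
a full grid is exponential in the number of regions). Mutations fall to the
basin of the candidate under which their read counts are most likely;
basins holding under 0.5% of mutations are dissolved.

A finite chain fragments true clusters into adjacent minor modes that
memorise binomial noise. Candidate basins are therefore consolidated by a
model-selection test: a pair is merged whenever separating them gains less
*soft mixture* log-likelihood than the BIC cost of one extra component
(its per-region CCF vector plus a weight, `0.5·(S+1)·log n`). Centroids in
this test (and in the output) are count-based ratio MLEs
`Σalt / Σ(depth·coef)`, so the test sees the data rather than the chain's
label history. Hard-assignment likelihoods cannot be used here: a hard
split on pure noise always gains likelihood, the soft mixture does not.

Convergence heuristic: the chain is flagged (not failed) when the occupied-
component count over the last half of the chain leaves a ±2 band around its
mode in more than 40% of sweeps.

### Cluster-removal rules

1. clusters holding < 1% of mutations;
2. chromosome-localized clusters — ≥ 50% of a cluster's mutations on ≤ 2
   chromosomes, applied to clusters of ≥ 20 mutations (the qualitative rule
   "most mutations on a small number of chromosomes" needs a concrete
   threshold; both numbers are configurable);
3. pigeonhole conflicts — a cluster whose centroid exceeds the truncal
   cluster's (the cluster closest to CCF 1 everywhere) in any sample beyond
   ε = max(0.05, 2× the centroid's binomial standard error). The
   depth-aware ε avoids over-pruning at low coverage.

Freed mutations are reassigned to the surviving cluster with the highest
read-count likelihood; every removal is recorded in an audit log.

## Clone-tree inference

Trees are rooted at the truncal cluster (min CCF across samples ≥ 0.9,
else an error). The score of a candidate tree sums, per sample: lineage
excess (child over parent beyond ε), pigeonhole excess (sibling sum over
parent beyond ε) and, for every ancestor–descendant pair, a crossing
penalty (positive only when the pair's CCF ordering flips beyond ε in both
directions). ε defaults to 0.05. For up to 8 clusters every labeled rooted
tree is enumerated (Prüfer sequences) and the minimum-score tree returned,
ties broken by shallower depth then lexicographic parent vector; from 9
clusters the enumeration (≥ 4.8M trees) is replaced by greedy insertion in
descending mean CCF, documented as approximate.

Labels: trunk = CCF ≥ 0.9 in all samples; leaf = present (CCF > 0.1) in
exactly one sample; else internal branch. The presence threshold 0.1 is a
choice (presence language has no universal cutoff) and is exposed. The
oval-plot matrix (cluster × sample CCF, samples in spatial order, clusters
ordered trunk/branch/leaf) is emitted alongside.

Metastasis seeding is annotated as the primary region(s) sharing the most
non-truncal clusters with the metastasis sample.

## Event timing

Under constant-rate mutation accrual, a duplication at relative molecular
time `t` duplicates the mutations that preceded it on the gained copy:
for a 2+1 gain `N2 = r·t`, `N1 = r·(3−2t)`, hence `t = 3·N2/(N1+2·N2)`;
for copy-neutral LOH (2+0) `N2 = r·t`, `N1 = 2r(1−t)`, hence
`t = 2·N2/(N1+2·N2)`. Only clonal (truncal) mutations inside the gained
segment count; a minimum support of 10 informative mutations is required,
and `t` is clamped to [0, 1]. Mutation-vs-LOH ordering: in a 2+0 segment a
clonal mutation at multiplicity 2 predates the LOH, multiplicity 1
postdates it; in a 2+1 gain multiplicity 2 means "before", while
multiplicity 1 supports "after" only when the gain itself is timed early
(t < 0.5) — otherwise the mutation may simply sit on the un-gained allele
and the call is undetermined.

## ITH metrics

* **Presence call**: a mutation is present in a sample at ≥ 3 alt reads and
  VAF ≥ 0.05 (configurable; no universal thresholds exist for this call).
* **APITH** = mean over all unordered sample pairs of the count of
  mutations present in exactly one of the pair. Because it averages over
  pairs it does not grow with the number of samples — the property the
  acceptance suite verifies by subsampling and doubling region counts.
* **SCNA clonality** partitions the genome at the union of segment
  breakpoints; an atomic interval covered in every region is diploid
  ((total, minor) = (2,1) everywhere), clonal (non-diploid and identical
  across regions) or subclonal (non-diploid somewhere and differing).
  Fractions are over the callable genome (covered in all regions) and close
  to 1 exactly — integer base-pair arithmetic, no floats. The within-sample
  `clonal_fraction` field of segments is deliberately ignored: clonality
  here is defined by cross-region sharing.
* **SCNA sizes**: one-sided Wilcoxon rank-sum (clonal > subclonal),
  exact for ≤ 8 events per group.
* **SV clonality**: an event is clonal iff present in every tumor sample;
  breakpoints match within ±100 bp (no tolerance is standard; configurable).
* **Methylation variability**: per probe, range = max − min beta over the
  chosen sample group; per genomic context, the median of member-probe
  ranges. Inter-individual variability uses normal samples only.
* **Top-variable probes**: ranked by intratumor range over tumor samples
  (normals excluded), top ⌈fraction·P⌉ kept, ties at the cutoff broken by
  lexicographic probe ID (determinism).
* **Congruence**: SNV pairwise distances restricted to non-truncal
  mutations; methylation Euclidean distances on the top 5,000 most variable
  probes; Spearman's rho across pairs. Pairs may be pooled across the
  tumors of a cohort, which is how the cohort-level validation runs it —
  a single tumor's handful of pairs gives the null correlation no
  resolution. P-values: exact permutation enumeration for ≤ 10 pairs, the
  t-distribution approximation above (a standard large-sample substitute
  for the classical small-sample series approximation).
* **Methylation clustering**: Ward linkage on Euclidean distances
  (scipy), samples pre-sorted by ID for deterministic leaf order; the
  tumor/normal separation score is the fraction of normals in the
  normal-majority flat cluster at k = 2.

## Filters

Thresholds are applied with the exact strictness of their definitions:
indels pass at tumor alt fraction > 0.04 (strict), normal alt fraction
< 0.02 (strict), tumor depth ≥ 8, normal depth ≥ 6, tumor alt reads > 3
(strict); targeted sequencing at depth ≥ 30 and alt reads ≥ 8. The driver
rule requires a configured driver-gene list and either a deleterious
consequence (stop-gain, frameshift, splicing, or missense judged by score)
with SIFT < 0.05 or PolyPhen > 0.995 or a [0,1]-normalized CADD-like score
> 0.99, or a recurrent / 3D-clustered hotspot flag; with no scores and no
hotspot flags the variant is "not-classifiable", distinct from non-driver.
The shipped driver-gene list is a small illustrative kidney-cancer set, not
a full targeted panel. Hyper/hypo-methylation is a ±0.20 *absolute* beta
change against the matched reference normal by default; the wording "20%
in-/decrease relative to the matched normal" is ambiguous, so a
`relative=True` switch implements the multiplicative reading. When several
normals exist, the designated reference is the most distant one.

## The synthetic-data generator

`SimConfig` defaults encode the emulated study design: 1–10 regions
(default 4) plus optional metastases, per-region purity drawn U(0.2, 0.9)
when not supplied, Poisson-60X depth, ~70% truncal mutations, clonal
arm-level SCNAs (on a 22-autosome genome with hg19 arm proportions scaled
down 100×) with subclonal focal events 1–5% of a chromosome, SV type
frequencies matching observed renal-tumor proportions (tandem duplication
36.4%, translocation 34.0%, deletion 29.4%) with a 40% clonal share, and
10,000 methylation probes.

Tree topology is uniform via random parent assignment among existing
nodes. CCFs are allocated per region by stick-breaking of the parent's
CCF with Beta(4, 1) stick fractions — children consume most of their
parent, which both matches the large subclone CCFs seen in multi-region
renal studies and makes chains identifiable (a chain's sibling
rearrangement then violates the pigeonhole sum). Allocations below CCF 0.1
are censored to absent (a subclone at CCF < 0.1 yields ~2 alt reads at 60X
and is undetectable); a cluster absent everywhere is instead given a share
of its parent's slack in the parent's best region. Spatial structure:
non-motile subclones occupy a contiguous block of the sampling axis; with
probability `intermix_prob` a subclone is motile and occupies an arbitrary
region subset. Post-conditions guaranteed constructively: the pigeonhole
principle in every region; at least one region-restricted cluster when
≥ 3 regions; when intermixing is enabled, at least one subclone at
subclonal CCF in two non-adjacent regions.

Truncal mutations falling in a timed clonal duplication receive
multiplicity 2 with the accrual probability `t/(3−t)` (2+1) or `t/(2−t)`
(2+0), so downstream gain timing can be validated end to end.

Methylation: a configurable fraction of probes carries a subclone-linked
effect — each signal probe is tied round-robin to one non-truncal cluster
and shifted by ±0.25 beta in every sample where that subclone is present,
the sign chosen away from the nearer boundary so the effect is never
clipped. Baselines sit on a dyadic grid (multiples of 1/1024) so the shift
is exact in floating point and equal effects give exactly equal probe
ranges — this makes the noise-free, full-signal case an exact monotone
transform of the subclonal-SNV distances (congruence rho = 1), a property
the tests rely on. Noise is additive Gaussian on the logit scale (σ = 0.3),
which keeps betas in (0, 1) with roughly beta-like variance; normal columns
carry baseline plus noise only, no subclone effects.

**What the generator does not emulate**: sequencing error and mapping
artifacts, trinucleotide mutation signatures, subclonal copy-number states
within one sample (segments carry a single state), kataegis/chromothripsis
SV clustering, probe-level array noise structure, and spatial
agent-based growth. Passing tests therefore demonstrate correctness of the
estimators under the stated generative model, not robustness to every
artifact of real data.

### Benchmark tumors

Recovery experiments use `clonalith.benchmark`, which rejection-samples
generator draws until (a) all cluster CCF vectors are ≥ 0.2 apart
(max-norm) and (b) the true tree is the unique optimum of the constraint
score at the noise-free CCFs. Non-identifiable configurations — a chain
whose sibling rearrangement also satisfies every constraint — measure
tie-break luck rather than algorithm correctness, so they are excluded
from recovery scoring (they still appear in the constraint-enforcement
checks). Benchmark purity is fixed at 0.7, the histological inclusion
floor of multi-region designs (> 70% tumor nuclei).

## Problem sizes

Validation runs at desk scale, chosen to keep the full suite within
minutes on one CPU: 20 benchmark tumors (3 regions, 4 clusters, 150
mutations/cluster, 60X) for clustering and tree recovery; 1,000 random
feasible CCF matrices for constraint enforcement; 180 accrual draws per
gain type for timing; 100 six-region tumors for APITH invariance; 100
cohorts of 14 six-region tumors (8,000 probes each, top 5,000 used) per
congruence condition. The genome is the 100×-scaled autosome model
throughout.

## Known limitations

* Hard basin assignment truncates cluster tails; at cluster separations
  near the noise scale this biases adjacent centroids toward each other
  (visible when clusters are < ~0.15 apart at 60X).
* The exhaustive tree search is capped at 8 clusters; larger trees use a
  greedy construction without optimality guarantees.
* Gain timing assumes constant mutation rate and a single duplication
  event; whole-genome doubling is out of scope.
* The congruence p-value for > 10 pairs uses the t approximation, and
  pooled pairs are treated as exchangeable across tumors (within-tumor
  dependence mildly inflates its nominal precision).
* The DP sampler treats multiplicity and copy number as fixed inputs from
  the CCF step; mutation-copy-number phasing is not modelled.
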