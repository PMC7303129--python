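"""Synthetic multi-region tumor generator with known ground truth.

Emulates the study design of several samples taken at ~1.5 cm spacing from
the tumor center to the periphery (plus optional adrenal metastases and a
distant normal): a rooted subclone tree whose per-region cancer cell
fractions (CCFs) obey the pigeonhole principle by construction, spatial
intermixing of subclones, clonal arm-level plus subclonal focal copy-number
alterations, subclonal structural variants, ~60X read counts drawn through
the forward VAF equation, and methylation beta values whose inter-sample
distances track subclonal SNV distances.

Every entry point is deterministic given a seed: the same seed yields
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationError
from .io import (
    METH_CONTEXTS, BetaMatrix, MultiRegionVariantSet, Sample, SampleManifest,
    SegmentProfile, SVSet, TumorBundle, write_bundle,
)
from .model import expected_vaf

# hg19 autosome lengths and approximate centromere positions, scaled down
# 100x to a desk-scale genome (~28.8 Mb total).
_HG19_LENGTHS = [
    249250621, 243199373, 198022430, 191154276, 180915260, 171115067,
    159138663, 146364022, 141213431, 135534747, 135006516, 133851895,
    115169878, 107349540, 102531392, 90354753, 81195210, 78077248,
    59128983, 63025520, 48129895, 51304566,
]
_HG19_CENTROMERES = [
    125000000, 93300000, 91000000, 50400000, 48400000, 61000000, 59900000,
    45600000, 49000000, 40200000, 53700000, 35800000, 17900000, 17600000,
    19000000, 36600000, 24000000, 17200000, 26500000, 27500000, 13200000,
    14700000,
]
_SCALE = 100


def default_genome() -> pd.DataFrame:
    """22 autosomes with hg19 arm structure scaled down 100x."""
    return pd.DataFrame({
        "chrom": [f"chr{i}" for i in range(1, 23)],
        "length": [l // _SCALE for l in _HG19_LENGTHS],
        "centromere": [c // _SCALE for c in _HG19_CENTROMERES],
    })


@dataclass
class SimConfig:
    """Study-design parameters of one synthetic tumor.

    Defaults follow the study conditions: ~60X whole-genome coverage
    (Poisson), per-region purity drawn from the 0.2-0.9 envelope when not
    given, ~70% of mutations truncal, clonal arm-level plus subclonal focal
    SCNAs, and 40% of SVs shared by all regions.
    """

    n_regions: int = 4
    n_clusters: int = 5
    n_mutations: int = 600
    mean_depth: float = 60.0
    purity_per_region: Sequence[float] | float | None = None
    intermix_prob: float = 0.3
    seed: int = 0
    genome_model: pd.DataFrame = field(default_factory=default_genome)
    n_arm_scnas: int = 4
    n_focal_scnas: int = 6
    n_svs: int = 10
    n_probes: int = 10000
    n_metastases: int = 0
    # mutation allocation: either a trunk weight or explicit per-cluster counts
    trunk_weight: float = 0.7
    mutations_per_cluster: Sequence[int] | int | None = None
    # spatial structure
    stick_a: float = 4.0          # Beta(a, b) stick fraction; high consumption
    stick_b: float = 1.0
    min_presence_ccf: float = 0.1  # allocations below this are censored to absent
    block_min_fraction: float = 0.3   # non-motile subclones span a contiguous block
    motile_presence_prob: float = 0.6
    # SCNA / SV knobs
    focal_min_fraction: float = 0.01  # focal event size as a fraction of the chromosome
    focal_max_fraction: float = 0.05
    sv_clonal_prob: float = 0.4
    # methylation knobs
    meth_signal_fraction: float = 0.5
    meth_effect: float = 0.25        # beta-scale shift per carried subclone
    meth_noise_sd: float = 0.3       # additive Gaussian noise on the logit scale
    n_normals: int = 1

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise ConfigError("n_clusters must be >= 1")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be > 0")
        if (self.genome_model["length"] <= 0).any():
            raise ConfigError("chromosome lengths must be > 0")
        purities = self.resolved_purities(np.random.default_rng(0))
        if np.any(purities <= 0) or np.any(purities > 1):
            raise ConfigError("purities must lie in (0, 1]")

    def resolved_purities(self, rng: np.random.Generator) -> np.ndarray:
        n = self.n_regions + self.n_metastases
        if self.purity_per_region is None:
            return rng.uniform(0.2, 0.9, size=n)
        if np.isscalar(self.purity_per_region):
            return np.full(n, float(self.purity_per_region))
        arr = np.asarray(self.purity_per_region, dtype=float)
        if len(arr) != n:
            raise ConfigError("purity_per_region length must match regions + metastases")
        return arr

    def cluster_sizes(self) -> np.ndarray:
        k = self.n_clusters
        if self.mutations_per_cluster is not None:
            if np.isscalar(self.mutations_per_cluster):
                return np.full(k, int(self.mutations_per_cluster))
            arr = np.asarray(self.mutations_per_cluster, dtype=int)
            if len(arr) != k:
                raise ConfigError("mutations_per_cluster length must equal n_clusters")
            return arr
        if k == 1:
            return np.array([self.n_mutations])
        trunk = int(round(self.trunk_weight * self.n_mutations))
        rest = self.n_mutations - trunk
        per = rest // (k - 1)
        sizes = np.full(k, per)
        sizes[0] = trunk + (rest - per * (k - 1))
        return sizes


@dataclass
class GroundTruth:
    """Generative truth of one synthetic tumor."""

    parent: np.ndarray                 # parent index per cluster; root = -1
    cluster_ccf: np.ndarray            # clusters x samples (regions + metastases)
    mutation_cluster: np.ndarray       # cluster index per mutation
    region_names: list[str]
    purity: np.ndarray                 # per sample
    loci: pd.DataFrame | None = None   # chrom/pos per mutation (set by simulate_reads)
    multiplicity: np.ndarray | None = None  # mutations x samples
    scna_events: pd.DataFrame | None = None  # one row per SCNA event
    gain_time: dict = field(default_factory=dict)  # event id -> t in [0,1]
    sv_clonality: pd.Series | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.parent)

    @property
    def n_regions(self) -> int:
        return self.cluster_ccf.shape[1]

    @property
    def scna_clonality(self) -> pd.Series | None:
        if self.scna_events is None:
            return None
        return self.scna_events["clonality"]

    def check_pigeonhole(self, tol: float = 1e-9) -> bool:
        """Constructive invariant: per sample, children CCFs sum to at most
        the parent's CCF, and the root is clonal everywhere."""
        ccf = self.cluster_ccf
        if not np.allclose(ccf[0], 1.0, atol=tol):
            return False
        for p in range(self.n_clusters):
            kids = np.flatnonzero(self.parent == p)
            if kids.size and np.any(ccf[kids].sum(axis=0) > ccf[p] + tol):
                return False
        for k in range(1, self.n_clusters):
            if np.any(ccf[k] > ccf[self.parent[k]] + tol):
                return False
        return True


# ---------------------------------------------------------------------------
# tree + CCF matrix
# ---------------------------------------------------------------------------

def _scale_subtree(ccf: np.ndarray, parent: np.ndarray, node: int, region: int,
                   factor: float) -> None:
    stack = [node]
    while stack:
        u = stack.pop()
        ccf[u, region] *= factor
        stack.extend(np.flatnonzero(parent == u).tolist())


def _presence_masks(parent: np.ndarray, n_regions: int, intermix_prob: float,
                    cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-cluster region presence; non-motile subclones occupy a contiguous
    block of the center-to-periphery sampling axis, motile ones an arbitrary
    region subset (spatial intermixing)."""
    k = len(parent)
    masks = np.ones((k, n_regions), dtype=bool)
    for c in range(1, k):
        if rng.random() < intermix_prob:
            m = rng.random(n_regions) < cfg.motile_presence_prob
            if not m.any():
                m[rng.integers(n_regions)] = True
        else:
            length = max(1, int(round(n_regions * rng.uniform(cfg.block_min_fraction, 1.0))))
            start = int(rng.integers(0, n_regions - length + 1))
            m = np.zeros(n_regions, dtype=bool)
            m[start:start + length] = True
        masks[c] = m
    return masks


def _region_ccfs(parent: np.ndarray, n_regions: int, cfg: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Stick-breaking allocation of CCF down the tree, per region, masked by
    spatial presence. Pigeonhole holds by construction."""
    k = len(parent)
    masks = _presence_masks(parent, n_regions, cfg.intermix_prob, cfg, rng)
    ccf = np.zeros((k, n_regions))
    ccf[0] = 1.0
    children = [np.flatnonzero(parent == p) for p in range(k)]
    for r in range(n_regions):
        for p in range(k):
            remaining = ccf[p, r]
            for c in children[p]:
                frac = rng.beta(cfg.stick_a, cfg.stick_b)
                val = remaining * frac if masks[c, r] else 0.0
                if val < cfg.min_presence_ccf:
                    val = 0.0   # below the read-depth detectability floor
                ccf[c, r] = val
                remaining -= val
    return ccf


def _ensure_every_cluster_present(ccf: np.ndarray, parent: np.ndarray,
                                  rng: np.random.Generator) -> None:
    """No cluster may be absent from every region: give an all-zero cluster
    a share of its parent's slack in the parent's best region."""
    k, n_regions = ccf.shape
    for c in range(1, k):
        if ccf[c].any():
            continue
        p = parent[c]
        kids = np.flatnonzero(parent == p)
        slack = ccf[p] - ccf[kids].sum(axis=0)
        r = int(np.argmax(slack))
        if slack[r] > 0.125:
            ccf[c, r] = max(slack[r] * rng.uniform(0.4, 0.8), 0.1)
        else:
            # free a quarter of the parent by scaling sibling subtrees
            r = int(np.argmax(ccf[p]))
            if ccf[p, r] <= 0:
                continue
            target = 0.25 * ccf[p, r]
            sib_sum = ccf[kids, r].sum()
            if sib_sum > 0:
                f = (ccf[p, r] - target) / sib_sum
                for s in kids:
                    _scale_subtree(ccf, parent, int(s), r, f)
            ccf[c, r] = target


def _ensure_region_restricted(ccf: np.ndarray, parent: np.ndarray) -> None:
    k, n_regions = ccf.shape
    if k < 2 or n_regions < 3:
        return
    present = ccf > 0
    if np.any(present[1:].sum(axis=1) == 1):
        return
    # force the last cluster (always childless) into its best single region
    c = k - 1
    if not present[c].any():
        return
    keep = int(np.argmax(ccf[c]))
    ccf[c, :] = np.where(np.arange(n_regions) == keep, ccf[c], 0.0)


def _ensure_intermixing(ccf: np.ndarray, parent: np.ndarray,
                        rng: np.random.Generator) -> None:
    """Guarantee some subclone at subclonal CCF in >= 2 non-adjacent regions
    (index gap >= 2), disturbing the natural allocation as little as
    possible: the widest-spread subclone gains presence in one extra region
    out of its parent's slack."""
    k, n_regions = ccf.shape
    if k < 2 or n_regions < 3:
        return
    parent_ccf = np.vstack([np.ones(n_regions)] +
                           [ccf[parent[c]] for c in range(1, k)])
    sub = (ccf > 1e-9) & (ccf < parent_ccf - 1e-9)
    for c in range(1, k):
        regs = np.flatnonzero(sub[c])
        if regs.size >= 2 and regs.max() - regs.min() >= 2:
            return
    # no natural intermixing: extend a child of the root (its parent is
    # present everywhere, so raising it can never break the lineage rule)
    root_kids = np.flatnonzero(parent == 0)
    c = int(max(root_kids, key=lambda x: (sub[x].sum(), -x)))
    regs = np.flatnonzero(sub[c])
    anchor = int(regs[0]) if regs.size else 0
    far = 0 if anchor >= 2 else n_regions - 1
    if abs(far - anchor) < 2:
        anchor, far = 0, n_regions - 1
    for r in (anchor, far):
        if sub[c, r]:
            continue
        slack = 1.0 - ccf[root_kids, r].sum()
        if slack > 1e-6:
            val = slack * rng.uniform(0.4, 0.8)
        else:
            val = 0.25
            sib_sum = ccf[root_kids, r].sum() - ccf[c, r]
            f = (1.0 - val) / sib_sum if sib_sum > 0 else 1.0
            for s in root_kids:
                if s != c:
                    _scale_subtree(ccf, parent, int(s), r, f)
        old = ccf[c, r]
        if old > 0:
            _scale_subtree(ccf, parent, c, r, min(val, 0.9) / old)
        else:
            ccf[c, r] = min(val, 0.9)  # subtree of c is zero here


def simulate_tree(config: SimConfig, rng: np.random.Generator | None = None,
                  min_gap: float = 0.0, max_tries: int = 200) -> GroundTruth:
    """Draw a rooted subclone tree and per-region CCF matrix.

    Topology is uniform via random parent assignment among existing nodes;
    CCFs come from stick-breaking of the parent's CCF, so the pigeonhole
    principle holds by construction. ``min_gap`` > 0 rejects draws until all
    cluster CCF vectors are at least that far apart (max-norm), for
    well-separated benchmark tumors.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    k, n_regions = config.n_clusters, config.n_regions
    n_samples = n_regions + config.n_metastases
    for _ in range(max_tries):
        parent = np.full(k, -1, dtype=int)
        for c in range(1, k):
            parent[c] = int(rng.integers(0, c))
        ccf = _region_ccfs(parent, n_samples, config, rng)
        _ensure_every_cluster_present(ccf, parent, rng)
        _ensure_region_restricted(ccf[:, :n_regions], parent)
        if config.intermix_prob > 0:
            _ensure_intermixing(ccf, parent, rng)
        if min_gap > 0 and k > 1:
            d = np.abs(ccf[:, None, :] - ccf[None, :, :]).max(axis=2)
            if (d[np.triu_indices(k, 1)] < min_gap).any():
                continue
        break
    else:
        raise SimulationError(f"could not satisfy min_gap={min_gap} in {max_tries} tries")

    sizes = config.cluster_sizes()
    mutation_cluster = np.repeat(np.arange(k), sizes)
    names = [f"T{i + 1:02d}" for i in range(n_regions)] + \
            [f"M{i + 1:02d}" for i in range(config.n_metastases)]
    return GroundTruth(
        parent=parent, cluster_ccf=ccf, mutation_cluster=mutation_cluster,
        region_names=names, purity=config.resolved_purities(rng),
    )


def extend_regions(truth: GroundTruth, config: SimConfig, n_extra: int,
                   rng: np.random.Generator) -> GroundTruth:
    """Append ``n_extra`` freshly sampled region columns on the same tree
    (used to test sample-number invariance of ITH metrics)."""
    extra = _region_ccfs(truth.parent, n_extra, config, rng)
    extra[0] = 1.0
    start = truth.cluster_ccf.shape[1]
    names = truth.region_names + [f"T{start + i + 1:02d}" for i in range(n_extra)]
    if config.purity_per_region is None:
        pur = rng.uniform(0.2, 0.9, size=n_extra)
    elif np.isscalar(config.purity_per_region):
        pur = np.full(n_extra, float(config.purity_per_region))
    else:
        pur = np.full(n_extra, float(np.mean(config.purity_per_region)))
    return GroundTruth(
        parent=truth.parent.copy(),
        cluster_ccf=np.hstack([truth.cluster_ccf, extra]),
        mutation_cluster=truth.mutation_cluster.copy(),
        region_names=names,
        purity=np.concatenate([truth.purity, pur]),
    )


# ---------------------------------------------------------------------------
# SCNAs
# ---------------------------------------------------------------------------

_ARM_TYPES = [("gain", 3, 2, 1, "ASCNA"), ("nloh", 2, 2, 0, "NLOH"),
              ("loss", 1, 1, 0, "DLOH")]
_FOCAL_TYPES = [("gain", 3, 2, 1, "ASCNA"), ("loss", 1, 1, 0, "DLOH")]


def simulate_scnas(truth: GroundTruth, config: SimConfig,
                   rng: np.random.Generator | None = None) -> SegmentProfile:
    """Arm-level events identical across all regions (clonal, with a gain
    time for duplications) plus smaller focal events restricted to proper
    region subsets (subclonal). Returns the full segment profile; event
    labels and gain times are stored on ``truth``."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genome = config.genome_model
    if len(genome) == 0:
        raise ConfigError("genome model is empty")
    n_samples = len(truth.region_names)
    all_regions = tuple(range(n_samples))

    arms = []
    for _, row in genome.iterrows():
        arms.append((row["chrom"], 1, int(row["centromere"])))
        arms.append((row["chrom"], int(row["centromere"]) + 1, int(row["length"])))
    events = []
    picked = rng.choice(len(arms), size=min(config.n_arm_scnas, len(arms)), replace=False)
    for ai in picked:
        chrom, start, end = arms[ai]
        kind, total, major, minor, state = _ARM_TYPES[rng.integers(len(_ARM_TYPES))]
        t = float(rng.uniform(0.1, 0.9)) if kind in ("gain", "nloh") else None
        events.append(dict(chrom=chrom, start=start, end=end, scale="arm",
                           change=kind, total=total, major=major, minor=minor,
                           state=state, regions=all_regions, clonality="clonal",
                           gain_time=t))

    occupied: dict[str, list[tuple[int, int]]] = {}
    for ev in events:
        occupied.setdefault(ev["chrom"], []).append((ev["start"], ev["end"]))
    n_focal_placed = 0
    tries = 0
    while n_focal_placed < config.n_focal_scnas and tries < 100 * max(config.n_focal_scnas, 1):
        tries += 1
        row = genome.iloc[int(rng.integers(len(genome)))]
        chrom, length = row["chrom"], int(row["length"])
        size = max(2, int(round(length * rng.uniform(config.focal_min_fraction,
                                                     config.focal_max_fraction))))
        start = int(rng.integers(1, max(2, length - size)))
        end = start + size - 1
        if any(s <= end and start <= e for s, e in occupied.get(chrom, [])):
            continue
        kind, total, major, minor, state = _FOCAL_TYPES[rng.integers(len(_FOCAL_TYPES))]
        if n_samples > 1:
            n_in = int(rng.integers(1, n_samples))  # proper, non-empty subset
            regions = tuple(sorted(rng.choice(n_samples, size=n_in, replace=False).tolist()))
        else:
            regions = (0,)
        occupied.setdefault(chrom, []).append((start, end))
        events.append(dict(chrom=chrom, start=start, end=end, scale="focal",
                           change=kind, total=total, major=major, minor=minor,
                           state=state, regions=regions, clonality="subclonal",
                           gain_time=None))
        n_focal_placed += 1

    rows = []
    for si, sample in enumerate(truth.region_names):
        for _, g in genome.iterrows():
            chrom, length = g["chrom"], int(g["length"])
            here = sorted((ev for ev in events
                           if ev["chrom"] == chrom and si in ev["regions"]),
                          key=lambda e: e["start"])
            cursor = 1
            for ev in here:
                if ev["start"] > cursor:
                    rows.append([sample, chrom, cursor, ev["start"] - 1, 2, 1, 1, 1.0, "HET"])
                rows.append([sample, chrom, ev["start"], ev["end"], ev["total"],
                             ev["major"], ev["minor"], 1.0, ev["state"]])
                cursor = ev["end"] + 1
            if cursor <= length:
                rows.append([sample, chrom, cursor, length, 2, 1, 1, 1.0, "HET"])
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "total",
                                     "major", "minor", "frac", "state"])
    truth.scna_events = pd.DataFrame(events)
    truth.gain_time = {i: ev["gain_time"] for i, ev in enumerate(events)
                       if ev["gain_time"] is not None}
    return SegmentProfile(df)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _gain_mult2_prob(change: str, t: float) -> float:
    """Probability that a truncal mutation in a timed duplication carries
    multiplicity 2, under constant-rate accrual (gain at relative time t)."""
    if change == "gain":      # 2+1: N2 = rt of total r(3-t)
        return t / (3.0 - t)
    if change == "nloh":      # 2+0: N2 = rt of total r(2-t)
        return t / (2.0 - t)
    return 0.0


def simulate_reads(truth: GroundTruth, config: SimConfig,
                   segments: SegmentProfile | None = None,
                   rng: np.random.Generator | None = None,
                   include_normal: bool = True) -> MultiRegionVariantSet:
    """Draw per-region read counts through the forward VAF equation.

    Depth is Poisson(mean_depth); alt counts Binomial(depth, v) with
    v = m * phi * rho / (rho*CN + 2(1-rho)). With ``segments=None`` the
    genome is treated as diploid everywhere (fast path for experiments that
    do not involve SCNAs). Truncal mutations inside timed clonal
    duplications are assigned multiplicity 2 with the accrual probability,
    so gain timing can be recovered downstream.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    genome = config.genome_model
    n = len(truth.mutation_cluster)
    samples = truth.region_names
    n_s = len(samples)

    lengths = genome["length"].to_numpy(dtype=float)
    chrom_idx = rng.choice(len(genome), size=n, p=lengths / lengths.sum())
    pos = (rng.random(n) * lengths[chrom_idx]).astype(int) + 1
    chroms = genome["chrom"].to_numpy()[chrom_idx]

    total_cn = np.full((n, n_s), 2, dtype=int)
    mult = np.ones((n, n_s), dtype=int)
    if segments is not None:
        for si, sample in enumerate(samples):
            for m in range(n):
                seg = segments.locate(sample, chroms[m], int(pos[m]))
                if seg is None:
                    continue
                total_cn[m, si] = int(seg["total"])
        # timed clonal duplications: decide multiplicity once per mutation
        if truth.scna_events is not None:
            for ev_id, ev in truth.scna_events.iterrows():
                if ev["clonality"] != "clonal" or ev.get("gain_time") is None:
                    continue
                t = float(ev["gain_time"])
                inside = (chroms == ev["chrom"]) & (pos >= ev["start"]) & (pos <= ev["end"])
                truncal = truth.mutation_cluster == 0
                cand = np.flatnonzero(inside & truncal)
                dup = cand[rng.random(cand.size) < _gain_mult2_prob(ev["change"], t)]
                mult[dup, :] = 2

    phi = truth.cluster_ccf[truth.mutation_cluster]       # n x n_s
    rho = truth.purity[None, :]
    v = expected_vaf(phi, rho, total_cn, mult)
    if np.any(v > 1.0 + 1e-9):
        raise SimulationError("expected VAF > 1: multiplicity/copy-number inconsistent")
    v = np.clip(v, 0.0, 1.0)

    depth = rng.poisson(config.mean_depth, size=(n, n_s))
    alt = rng.binomial(depth, v)
    ref = depth - alt

    bases = np.array(list("ACGT"))
    refb = bases[rng.integers(0, 4, n)]
    altb = bases[(np.char.find("ACGT", refb.astype("U1")) +
                  rng.integers(1, 4, n)) % 4]
    variants = pd.DataFrame({
        "chrom": chroms, "pos": pos, "ref": refb, "alt": altb,
        "var_class": "SNV",
    })
    cols = list(samples)
    ref_df = pd.DataFrame(ref, columns=cols)
    alt_df = pd.DataFrame(alt, columns=cols)
    if include_normal:
        for i in range(config.n_normals):
            nname = f"N{i + 1:02d}"
            ref_df[nname] = rng.poisson(config.mean_depth, size=n)
            alt_df[nname] = 0
    truth.loci = variants[["chrom", "pos"]].copy()
    truth.multiplicity = mult
    return MultiRegionVariantSet(variants, ref_df, alt_df)


# ---------------------------------------------------------------------------
# SVs
# ---------------------------------------------------------------------------

_SV_TYPE_P = {"tandem_dup": 0.364, "translocation": 0.34, "deletion": 0.294,
              "inversion": 0.002}


def simulate_svs(truth: GroundTruth, config: SimConfig,
                 rng: np.random.Generator | None = None) -> SVSet:
    """Breakpoint-pair SVs; clonal events (shared by all regions) with
    probability ``sv_clonal_prob``, otherwise restricted to a proper subset."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    genome = config.genome_model
    samples = truth.region_names
    n_s = len(samples)
    types = list(_SV_TYPE_P)
    p = np.array([_SV_TYPE_P[t] for t in types])
    p = p / p.sum()
    rows, pres_rows, ccf_rows, labels = [], [], [], []
    for _ in range(config.n_svs):
        sv_type = types[int(rng.choice(len(types), p=p))]
        gi = int(rng.integers(len(genome)))
        chrom1 = genome.iloc[gi]["chrom"]
        len1 = int(genome.iloc[gi]["length"])
        pos1 = int(rng.integers(1, len1))
        if sv_type == "translocation":
            gj = int((gi + 1 + rng.integers(len(genome) - 1)) % len(genome))
            chrom2 = genome.iloc[gj]["chrom"]
            pos2 = int(rng.integers(1, int(genome.iloc[gj]["length"])))
            size = 0
        else:
            chrom2 = chrom1
            size = max(1, int(rng.lognormal(np.log(len1 * 0.01), 0.8)))
            pos2 = min(pos1 + size, len1)
            size = pos2 - pos1 if pos2 > pos1 else 1
            pos2 = pos1 + size
        clonal = rng.random() < config.sv_clonal_prob or n_s == 1
        if clonal:
            present = np.ones(n_s, dtype=bool)
            ccf = np.ones(n_s)
            labels.append("clonal")
        else:
            n_in = int(rng.integers(1, n_s))
            present = np.zeros(n_s, dtype=bool)
            present[rng.choice(n_s, size=n_in, replace=False)] = True
            ccf = np.where(present, rng.uniform(0.2, 0.8, n_s), 0.0)
            labels.append("subclonal")
        rows.append([chrom1, pos1, chrom2, pos2, sv_type, size])
        pres_rows.append(present)
        ccf_rows.append(ccf)
    events = pd.DataFrame(rows, columns=["chrom1", "pos1", "chrom2", "pos2",
                                         "sv_type", "size"])
    presence = pd.DataFrame(np.array(pres_rows, dtype=bool).reshape(-1, n_s),
                            columns=samples)
    ccf = pd.DataFrame(np.array(ccf_rows, dtype=float).reshape(-1, n_s),
                       columns=samples)
    truth.sv_clonality = pd.Series(labels)
    return SVSet(events, presence, ccf)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _logit(x):
    return np.log(x / (1.0 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(truth: GroundTruth, config: SimConfig,
                         rng: np.random.Generator | None = None) -> BetaMatrix:
    """Beta values whose inter-sample distances track subclonal SNV distances.

    A fraction of probes carry a subclone-linked effect: each signal probe is
    tied (round-robin) to one non-truncal cluster and shifted by a fixed
    magnitude in every sample where that subclone is present. Noise is
    additive Gaussian on the logit scale, so betas stay in (0, 1); normal
    columns get independent noise only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    if config.n_probes < 100:
        raise ConfigError("n_probes must be >= 100")
    p = config.n_probes
    samples = truth.region_names
    k = truth.n_clusters

    # dyadic baseline grid: adding a dyadic effect size is then exact in
    # floating point, so equal effects give exactly equal probe ranges
    base = rng.integers(154, 871, size=p) / 1024.0
    n_signal = int(round(config.meth_signal_fraction * p))
    probe_cluster = np.full(p, -1)
    if k > 1 and n_signal > 0:
        probe_cluster[:n_signal] = 1 + (np.arange(n_signal) % (k - 1))
    # shift away from the nearer beta boundary so the effect is never clipped
    sign = np.where(base <= 0.5, 1.0, -1.0)

    presence = truth.cluster_ccf > 0.0                      # k x n_samples
    shift = np.zeros((p, len(samples)))
    sig = probe_cluster >= 0
    if sig.any():
        shift[sig] = (sign[sig, None] * config.meth_effect *
                      presence[probe_cluster[sig]].astype(float))
    mean_beta = np.clip(base[:, None] + shift, 0.02, 0.98)
    if config.meth_noise_sd > 0:
        noise = rng.normal(0.0, config.meth_noise_sd, size=mean_beta.shape)
        tumor = _expit(_logit(mean_beta) + noise)
    else:
        tumor = mean_beta

    cols = {s: tumor[:, i] for i, s in enumerate(samples)}
    for i in range(config.n_normals):
        nb = np.clip(base, 0.02, 0.98)
        if config.meth_noise_sd > 0:
            nn = rng.normal(0.0, config.meth_noise_sd, size=p)
            cols[f"N{i + 1:02d}"] = _expit(_logit(nb) + nn)
        else:
            cols[f"N{i + 1:02d}"] = nb

    probes = [f"cg{i:07d}" for i in range(p)]
    values = pd.DataFrame(cols, index=pd.Index(probes, name="probe"))
    values = values.clip(0.0, 1.0)
    ann = pd.DataFrame({
        "context": rng.choice(np.array(METH_CONTEXTS, dtype=object), size=p),
        "cpg_island": rng.random(p) < 0.3,
    }, index=values.index)
    return BetaMatrix(values, ann)


# ---------------------------------------------------------------------------
# full tumor
# ---------------------------------------------------------------------------

def simulate_tumor(config: SimConfig, seed: int | None = None,
                   tumor_id: str = "SIM") -> tuple[TumorBundle, GroundTruth]:
    """Simulate a complete tumor bundle plus its ground truth."""
    if seed is not None:
        config = replace(config, seed=seed)
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = simulate_tree(config, rng)
    segments = simulate_scnas(truth, config, rng)
    variants = simulate_reads(truth, config, segments, rng)
    svs = simulate_svs(truth, config, rng)
    betas = simulate_methylation(truth, config, rng)

    samples = []
    for i, name in enumerate(truth.region_names):
        role = "metastasis" if name.startswith("M") else "primary"
        samples.append(Sample(name, role, purity=float(truth.purity[i]),
                              spatial_index=i + 1))
    for i in range(config.n_normals):
        samples.append(Sample(f"N{i + 1:02d}", "normal",
                              spatial_index=len(truth.region_names) + i + 1))
    manifest = SampleManifest(tumor_id=tumor_id, samples=samples)
    bundle = TumorBundle(manifest, variants, segments, svs, betas)
    return bundle, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Ground truth as a JSON sidecar next to the simulated bundle."""
    data = {
        "parent": truth.parent.tolist(),
        "cluster_ccf": truth.cluster_ccf.tolist(),
        "mutation_cluster": truth.mutation_cluster.tolist(),
        "region_names": truth.region_names,
        "purity": truth.purity.tolist(),
        "gain_time": {str(k): v for k, v in truth.gain_time.items()},
        "scna_clonality": (truth.scna_clonality.tolist()
                           if truth.scna_clonality is not None else None),
        "sv_clonality": (truth.sv_clonality.tolist()
                         if truth.sv_clonality is not None else None),
    }
    Path(path).write_text(json.dumps(data, indent=1) + "\n")


def simulate_to_dir(config: SimConfig, outdir: str | Path, seed: int | None = None,
                    tumor_id: str = "SIM") -> dict[str, Path]:
    """CLI entry: simulate a tumor and write bundle + ground-truth sidecar."""
    bundle, truth = simulate_tumor(config, seed=seed, tumor_id=tumor_id)
    contigs = dict(zip(config.genome_model["chrom"], config.genome_model["length"]))
    paths = write_bundle(bundle, outdir, contigs=contigs)
    gt = Path(outdir) / "ground_truth.json"
    write_ground_truth(truth, gt)
    paths["ground_truth"] = gt
    return paths
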