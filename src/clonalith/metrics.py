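"""Intratumor-heterogeneity statistics.

Covers the per-tumor heterogeneity summaries: APITH (average pairwise ITH,
the mean over all sample pairs of the count of mutations private to one of
the pair — by construction insensitive to the number of samples), clonal vs
subclonal genome fractions from joint copy-number states across regions,
clonal-vs-subclonal SCNA size comparison, SV clonality by shared
breakpoints, per-genomic-context SNV ITH, methylation variability (median
probe range per context), top-variable-probe selection, hierarchical
methylation clustering (Euclidean / Ward), and the genomic-epigenomic
congruence test (Spearman correlation between pairwise subclonal-SNV and
methylation distances).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, spearmanr

from .errors import UndefinedMetricError
from .io import BetaMatrix, MultiRegionVariantSet, SegmentProfile, SVSet

log = logging.getLogger(__name__)

#: default presence call: a mutation is present in a sample with
#: at least this many alt reads and at least this VAF
MIN_ALT_READS = 3
MIN_VAF = 0.05

#: breakpoint matching window for SV sharing (bp)
SV_BREAKPOINT_WINDOW = 100


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample distances with a metric tag."""

    samples: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = self.values
        if v.shape[0] != v.shape[1] or not np.allclose(v, v.T):
            raise UndefinedMetricError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise UndefinedMetricError("distance matrix diagonal must be zero")
        if (v < 0).any():
            raise UndefinedMetricError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def pairs(self) -> pd.DataFrame:
        rows = [(self.samples[i], self.samples[j], self.values[i, j])
                for i, j in itertools.combinations(range(len(self.samples)), 2)]
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "distance"])


# ---------------------------------------------------------------------------
# presence and APITH
# ---------------------------------------------------------------------------

def presence_matrix(variants: MultiRegionVariantSet,
                    samples: Sequence[str] | None = None,
                    min_alt: int = MIN_ALT_READS,
                    min_vaf: float = MIN_VAF) -> pd.DataFrame:
    """Boolean mutation x sample presence calls from read counts."""
    samples = list(samples) if samples is not None else variants.samples
    alt = variants.alt_counts[samples].to_numpy(dtype=float)
    depth = variants.depth[samples].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1.0), 0.0)
    return pd.DataFrame((alt >= min_alt) & (vaf >= min_vaf),
                        index=variants.variants.index, columns=samples)


def snv_distance(presence: pd.DataFrame, subset=None) -> DistanceMatrix:
    """Pairwise discordance: number of mutations present in exactly one of
    the two samples (optionally restricted to ``subset`` rows)."""
    p = presence if subset is None else presence.loc[subset]
    x = p.to_numpy(dtype=float)
    d = squareform(pdist(x.T, metric="cityblock"))
    return DistanceMatrix(list(p.columns), d, "snv_discordance")


def apith(presence: pd.DataFrame, samples: Sequence[str] | None = None) -> float:
    """Average pairwise ITH: mean pairwise discordance over all unordered
    sample pairs of one tumor."""
    p = presence[list(samples)] if samples is not None else presence
    if p.shape[1] < 2:
        raise UndefinedMetricError("APITH needs at least 2 tumor samples")
    dm = snv_distance(p)
    return float(dm.condensed().mean())


# ---------------------------------------------------------------------------
# SCNA clonality
# ---------------------------------------------------------------------------

def _joint_state_partition(segments: SegmentProfile, samples: Sequence[str]):
    """Atomic genome intervals with the (total, minor) state vector across
    samples. Intervals not covered in every sample are dropped (uncallable).
    Yields (chrom, start, end, states) with 1-based inclusive coordinates."""
    df = segments.df[segments.df["sample"].isin(samples)]
    for chrom, grp in df.groupby("chrom", sort=False):
        cuts = np.unique(np.r_[grp["start"].to_numpy(), grp["end"].to_numpy() + 1])
        per_sample = {s: grp[grp["sample"] == s].sort_values("start") for s in samples}
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            states = []
            ok = True
            for s in samples:
                g = per_sample[s]
                starts = g["start"].to_numpy()
                i = int(np.searchsorted(starts, lo, side="right")) - 1
                if i < 0 or lo > g["end"].to_numpy()[i]:
                    ok = False
                    break
                row = g.iloc[i]
                states.append((int(row["total"]), int(row["minor"])))
            if ok:
                yield chrom, int(lo), int(hi - 1), tuple(states)


def scna_clonal_fraction(segments: SegmentProfile,
                         samples: Sequence[str] | None = None) -> dict:
    """Clonal / subclonal / unaltered genome fractions across regions.

    The genome is partitioned by the joint (total, minor) state vector:
    positions non-diploid in at least one region and identical across all
    regions are clonal; non-diploid somewhere and differing are subclonal.
    Fractions are over the callable genome and close exactly:
    clonal + subclonal + unaltered = 1.
    """
    if samples is None:
        samples = segments.samples
    if len(samples) < 2:
        raise UndefinedMetricError("clonality needs >= 2 regions")
    clonal = subclonal = unaltered = 0
    for chrom, lo, hi, states in _joint_state_partition(segments, samples):
        length = hi - lo + 1
        diploid = all(st == (2, 1) for st in states)
        if diploid:
            unaltered += length
        elif all(st == states[0] for st in states):
            clonal += length
        else:
            subclonal += length
    callable_len = clonal + subclonal + unaltered
    if callable_len == 0:
        raise UndefinedMetricError("zero callable genome across regions")
    return {
        "clonal_fraction": clonal / callable_len,
        "subclonal_fraction": subclonal / callable_len,
        "unaltered_fraction": unaltered / callable_len,
        "callable_bp": callable_len,
    }


def scna_events(segments: SegmentProfile,
                samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Non-diploid events (merged atomic runs of constant joint state) with
    clonal/subclonal labels and sizes, for the size comparison."""
    if samples is None:
        samples = segments.samples
    rows = []
    prev = None
    for chrom, lo, hi, states in _joint_state_partition(segments, samples):
        diploid = all(st == (2, 1) for st in states)
        if diploid:
            prev = None
            continue
        label = "clonal" if all(st == states[0] for st in states) else "subclonal"
        if prev is not None and prev["chrom"] == chrom and \
                prev["end"] + 1 == lo and prev["states"] == states:
            prev["end"] = hi
            continue
        prev = {"chrom": chrom, "start": lo, "end": hi, "states": states,
                "clonality": label}
        rows.append(prev)
    df = pd.DataFrame(rows)
    if len(df):
        df["size"] = df["end"] - df["start"] + 1
        df = df.drop(columns=["states"])
    return df


def compare_scna_sizes(clonal_sizes, subclonal_sizes, min_events: int = 3):
    """One-sided Wilcoxon rank-sum: clonal SCNAs larger than subclonal.

    Returns (statistic, p-value); raises when either group has fewer than
    ``min_events`` events.
    """
    c = np.asarray(clonal_sizes, dtype=float)
    s = np.asarray(subclonal_sizes, dtype=float)
    if len(c) < min_events or len(s) < min_events:
        raise UndefinedMetricError(
            f"need >= {min_events} events per group (got {len(c)}, {len(s)})")
    method = "exact" if (len(c) <= 8 and len(s) <= 8) else "auto"
    res = mannwhitneyu(c, s, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# SV clonality
# ---------------------------------------------------------------------------

def sv_clonality(svs: SVSet, tumor_samples: Sequence[str] | None = None) -> dict:
    """Per-event clonal/subclonal labels plus the shared fraction.

    An event is clonal iff its breakpoints are present (within the matching
    window) in every tumor sample. With zero events an empty summary is
    returned (not an error).
    """
    samples = list(tumor_samples) if tumor_samples is not None else svs.samples
    n = len(svs)
    if n == 0:
        return {"labels": pd.Series(dtype=object), "clonal_count": 0,
                "subclonal_count": 0, "shared_fraction": None,
                "mean_ccf": pd.Series(dtype=float)}
    pres = svs.presence[samples].to_numpy(dtype=bool)
    clonal = pres.all(axis=1)
    labels = pd.Series(np.where(clonal, "clonal", "subclonal"),
                       index=svs.events.index)
    mean_ccf = pd.Series(dtype=float)
    if svs.ccf is not None:
        mean_ccf = svs.ccf[samples].mean(axis=1)
    return {
        "labels": labels,
        "clonal_count": int(clonal.sum()),
        "subclonal_count": int((~clonal).sum()),
        "shared_fraction": float(clonal.mean()),
        "mean_ccf": mean_ccf,
    }


def match_sv_breakpoints(svs_a: pd.DataFrame, svs_b: pd.DataFrame,
                         window: int = SV_BREAKPOINT_WINDOW) -> np.ndarray:
    """For each event in ``svs_a``, whether a same-type event in ``svs_b``
    shares both breakpoints within ``window`` bp."""
    out = np.zeros(len(svs_a), dtype=bool)
    for i, a in svs_a.reset_index(drop=True).iterrows():
        m = ((svs_b["sv_type"] == a["sv_type"])
             & (svs_b["chrom1"] == a["chrom1"]) & (svs_b["chrom2"] == a["chrom2"])
             & ((svs_b["pos1"] - a["pos1"]).abs() <= window)
             & ((svs_b["pos2"] - a["pos2"]).abs() <= window))
        out[i] = bool(m.any())
    return out


# ---------------------------------------------------------------------------
# SNV ITH by genomic context
# ---------------------------------------------------------------------------

def snv_ith_by_context(context: Sequence, is_truncal: Sequence[bool],
                       min_support: int = 10) -> pd.DataFrame:
    """Per-context fraction of non-truncal mutations; contexts with fewer
    than ``min_support`` mutations are flagged low-support."""
    df = pd.DataFrame({"context": context, "truncal": np.asarray(is_truncal, bool)})
    rows = []
    for ctx, grp in df.groupby("context", sort=True):
        n = len(grp)
        rows.append({"context": ctx, "n": n,
                     "nontruncal_fraction": float((~grp["truncal"]).mean()),
                     "low_support": n < min_support})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def methylation_variability(beta: BetaMatrix, samples: Sequence[str]) -> pd.Series:
    """Median probe range (max - min beta across ``samples``) per genomic
    context. Contexts with zero probes are omitted with a warning."""
    if len(samples) < 2:
        raise UndefinedMetricError("variability needs >= 2 samples")
    vals = beta.values[list(samples)]
    ranges = vals.max(axis=1) - vals.min(axis=1)
    ctx = beta.probe_annotation["context"]
    out = {}
    for context in sorted(ctx.unique()):
        mask = ctx == context
        if not mask.any():
            log.warning("context %s has no probes; omitted", context)
            continue
        out[context] = float(ranges[mask.to_numpy()].median())
    return pd.Series(out, name="median_range")


def select_top_variable_probes(beta: BetaMatrix, fraction: float = 0.01,
                               tumor_samples: Sequence[str] | None = None,
                               n_top: int | None = None) -> list[str]:
    """Probes with the greatest intratumor beta range (tumor samples only;
    normals excluded). Returns the top ceil(fraction * P) (or ``n_top``)
    probe IDs; ties at the cutoff break to the lexicographically smaller ID.
    """
    if not tumor_samples:
        raise UndefinedMetricError("no tumor samples for probe selection")
    if not (n_top is not None or 0 < fraction <= 1):
        raise UndefinedMetricError("fraction must be in (0, 1]")
    vals = beta.values[list(tumor_samples)]
    ranges = vals.max(axis=1) - vals.min(axis=1)
    k = n_top if n_top is not None else math.ceil(fraction * len(ranges))
    k = min(k, len(ranges))
    order = sorted(ranges.index, key=lambda pid: (-ranges[pid], pid))
    return order[:k]


def beta_distance(beta: BetaMatrix, samples: Sequence[str],
                  probes: Sequence[str] | None = None) -> DistanceMatrix:
    vals = beta.values.loc[probes if probes is not None else beta.values.index,
                           list(samples)]
    d = squareform(pdist(vals.to_numpy().T, metric="euclidean"))
    return DistanceMatrix(list(samples), d, "beta_euclidean")


@dataclass
class MethylationClustering:
    linkage: np.ndarray
    samples: list[str]
    flat_k2: np.ndarray
    separation_score: float | None


def cluster_methylation(beta: BetaMatrix, probes: Sequence[str] | None = None,
                        samples: Sequence[str] | None = None,
                        normal_samples: Sequence[str] | None = None) -> MethylationClustering:
    """Agglomerative clustering (Euclidean distance, Ward linkage) of
    samples on the chosen probe set. Samples are pre-sorted by ID, so leaf
    order is deterministic at ties. The separation score is the fraction of
    normals falling in the normal-majority flat cluster at k=2."""
    samples = sorted(samples if samples is not None else beta.samples)
    if len(samples) < 3:
        raise UndefinedMetricError("clustering needs >= 3 samples")
    vals = beta.values.loc[probes if probes is not None else beta.values.index,
                           samples]
    z = hierarchy.linkage(vals.to_numpy().T, method="ward", metric="euclidean")
    flat = hierarchy.fcluster(z, 2, criterion="maxclust")
    score = None
    if normal_samples:
        normals = np.isin(samples, list(normal_samples))
        if normals.any():
            shares = [(flat[normals] == c).mean() for c in (1, 2)]
            majority = 1 + int(np.argmax(shares))
            score = float((flat[normals] == majority).mean())
    return MethylationClustering(linkage=z, samples=samples, flat_k2=flat,
                                 separation_score=score)


# ---------------------------------------------------------------------------
# genomic-epigenomic congruence
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n <= 10)."""
    n = len(x)
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = np.sqrt((cx**2).sum() * (cy**2).sum())
    hits = total = 0
    target = abs(rho_obs) - 1e-12
    chunk, buf = 200_000, []

    def flush(buf, hits, total):
        perm = np.asarray(buf)
        rhos = (cy[perm] @ cx) / denom
        return hits + int((np.abs(rhos) >= target).sum()), total + len(perm)

    for p in itertools.permutations(range(n)):
        buf.append(p)
        if len(buf) >= chunk:
            hits, total = flush(buf, hits, total)
            buf = []
    if buf:
        hits, total = flush(buf, hits, total)
    return hits / total


@dataclass
class CongruenceResult:
    rho: float
    p_value: float
    n_pairs: int
    pair_table: pd.DataFrame


def congruence_from_pairs(snv_d: np.ndarray, beta_d: np.ndarray,
                          exact_max: int = 10) -> CongruenceResult:
    """Spearman correlation across sample pairs between subclonal-SNV and
    methylation distances. Exact permutation p-value for up to ``exact_max``
    pairs, t-approximation beyond."""
    snv_d = np.asarray(snv_d, dtype=float)
    beta_d = np.asarray(beta_d, dtype=float)
    n = len(snv_d)
    if n < 6:
        raise UndefinedMetricError(f"congruence needs >= 6 pairs, got {n}")
    rho, p = spearmanr(snv_d, beta_d)
    if n <= exact_max:
        p = _spearman_exact_p(snv_d, beta_d, rho)
    table = pd.DataFrame({"snv_distance": snv_d, "beta_distance": beta_d})
    return CongruenceResult(rho=float(rho), p_value=float(p), n_pairs=n,
                            pair_table=table)


def congruence(presence: pd.DataFrame, is_truncal: Sequence[bool],
               beta: BetaMatrix, tumor_samples: Sequence[str],
               n_top: int = 5000) -> CongruenceResult:
    """Per-tumor congruence: SNV distances on non-truncal mutations vs
    Euclidean beta distances on the ``n_top`` most variable probes."""
    samples = list(tumor_samples)
    if len(samples) < 4:
        raise UndefinedMetricError("congruence needs >= 4 tumor samples")
    sub = presence.index[~np.asarray(is_truncal, dtype=bool)]
    snv_dm = snv_distance(presence[samples], subset=sub)
    probes = select_top_variable_probes(beta, tumor_samples=samples, n_top=n_top)
    beta_dm = beta_distance(beta, samples, probes)
    return congruence_from_pairs(snv_dm.condensed(), beta_dm.condensed())


def congruence_pairs(presence: pd.DataFrame, is_truncal: Sequence[bool],
                     beta: BetaMatrix, tumor_samples: Sequence[str],
                     n_top: int = 5000) -> pd.DataFrame:
    """Per-pair distance table for one tumor (for pooling across tumors,
    as in cohort-level congruence analyses)."""
    samples = list(tumor_samples)
    sub = presence.index[~np.asarray(is_truncal, dtype=bool)]
    snv_dm = snv_distance(presence[samples], subset=sub)
    probes = select_top_variable_probes(beta, tumor_samples=samples, n_top=n_top)
    beta_dm = beta_distance(beta, samples, probes)
    return pd.DataFrame({"snv_distance": snv_dm.condensed(),
                         "beta_distance": beta_dm.condensed()})
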