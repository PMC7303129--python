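"""Cancer cell fraction estimation and multi-sample mutation clustering.

The pipeline mirrors the standard multi-region subclonal-reconstruction
recipe: allele counts and local allele-specific copy number are converted to
per-sample CCFs; a truncated Dirichlet-process mixture with binomial
emissions (through the forward VAF equation) is Gibbs-sampled jointly across
the regions of a tumor; clone clusters are read off as local peaks in the
posterior mutation density and each mutation is assigned to the basin of the
peak it most likely belongs to; finally clusters are pruned by three
removal rules (tiny clusters, chromosome-localized clusters, clusters that
conflict with the pigeonhole principle).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError, PipelineError
from .io import MultiRegionVariantSet, SegmentProfile
from .model import round_half_up, vaf_coefficient

log = logging.getLogger(__name__)

#: CCF values above 1 beyond this are clamped and flagged
CCF_CLAMP = 1.2


# ---------------------------------------------------------------------------
# CCF computation
# ---------------------------------------------------------------------------

@dataclass
class CCFEstimate:
    """Per-(mutation, sample) CCF, multiplicity and expected VAF."""

    ccf: pd.DataFrame
    multiplicity: pd.DataFrame
    expected_vaf: pd.DataFrame
    clamped: pd.DataFrame
    coef: pd.DataFrame          # c such that expected VAF = c * CCF
    excluded: list = field(default_factory=list)  # variant idx without a segment

    @property
    def samples(self) -> list[str]:
        return list(self.ccf.columns)


def compute_ccf(alt, depth, rho, total_cn, major_cn):
    """Invert the forward VAF equation for one (mutation, sample).

    Multiplicity is the rounded mutation copy number, clamped to
    [1, major_cn]; ties (x.5) round half up. Returns
    (ccf, multiplicity, expected_vaf, clamped); CCF is clamped to
    ``CCF_CLAMP`` with a flag.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1.0), 0.0)
    rho = np.asarray(rho, dtype=float)
    total_cn = np.asarray(total_cn, dtype=float)
    major = np.maximum(np.asarray(major_cn, dtype=float), 1.0)
    a = vaf * (rho * total_cn + 2.0 * (1.0 - rho)) / rho
    mult = np.clip(round_half_up(a), 1.0, major)
    phi = np.where(a > 0, a / mult, 0.0)
    clamped = phi > CCF_CLAMP
    phi = np.minimum(phi, CCF_CLAMP)
    exp_vaf = mult * phi * rho / (rho * total_cn + 2.0 * (1.0 - rho))
    return phi, mult, exp_vaf, clamped


def compute_ccf_matrix(variants: MultiRegionVariantSet, segments: SegmentProfile,
                       purity: Mapping[str, float],
                       samples: Sequence[str] | None = None) -> CCFEstimate:
    """Vectorised CCF table for all variants across tumor samples.

    Mutations without a covering segment in some sample are excluded from
    clustering (logged)."""
    if samples is None:
        samples = [s for s in variants.samples if s in purity and purity[s] is not None]
    n = variants.n_variants
    alt = variants.alt_counts[list(samples)].to_numpy(dtype=float)
    depth = variants.depth[list(samples)].to_numpy(dtype=float)
    total = np.full((n, len(samples)), np.nan)
    major = np.full((n, len(samples)), np.nan)
    chroms = variants.variants["chrom"].to_numpy()
    poss = variants.variants["pos"].to_numpy()
    for j, s in enumerate(samples):
        for i in range(n):
            seg = segments.locate(s, chroms[i], int(poss[i]))
            if seg is not None:
                total[i, j] = seg["total"]
                major[i, j] = seg["major"]
    covered = ~np.isnan(total).any(axis=1)
    excluded = variants.variants.index[~covered].tolist()
    if excluded:
        log.warning("%d variants lack a covering segment; excluded from clustering",
                    len(excluded))
    rho = np.array([purity[s] for s in samples], dtype=float)[None, :]
    total_f = np.where(covered[:, None], total, 2.0)
    major_f = np.where(covered[:, None], major, 1.0)
    phi, mult, exp_vaf, clamped = compute_ccf(alt, depth, rho, total_f, major_f)
    coef = vaf_coefficient(rho, total_f, mult)
    idx = variants.variants.index
    mk = lambda a, **kw: pd.DataFrame(a, index=idx, columns=list(samples), **kw)
    return CCFEstimate(ccf=mk(phi), multiplicity=mk(mult), expected_vaf=mk(exp_vaf),
                       clamped=mk(clamped), coef=mk(coef), excluded=excluded)


# ---------------------------------------------------------------------------
# purity from VAF
# ---------------------------------------------------------------------------

@dataclass
class PurityEstimate:
    sample: str
    rho: float
    method: str             # "from_segments_input" | "from_vaf"
    mode_vaf: float | None = None
    clamped: bool = False


def estimate_purity_from_vaf(vafs, sample: str = "", min_snvs: int = 20,
                             bandwidth: float | None = None) -> PurityEstimate:
    """Purity from the VAF distribution of SNVs in diploid heterozygous
    segments: twice the mode of the highest-VAF density peak.

    In a copy-neutral sample a clonal heterozygous mutation sits at
    VAF = rho/2, so rho = 2 * mode. The result is clamped to [0.05, 1.0].
    """
    vafs = np.asarray(vafs, dtype=float)
    vafs = vafs[np.isfinite(vafs)]
    if len(vafs) < min_snvs:
        raise InsufficientDataError(
            f"need >= {min_snvs} copy-neutral SNVs, got {len(vafs)}")
    kde = gaussian_kde(vafs, bw_method=bandwidth)
    grid = np.linspace(0.0, max(0.75, vafs.max() + 0.05), 751)
    dens = kde(grid)
    # local maxima; keep those carrying at least 10% of the global peak
    is_max = np.r_[False, (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:]), False]
    peaks = np.flatnonzero(is_max)
    peaks = peaks[dens[peaks] >= 0.1 * dens.max()]
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
    mode = float(grid[peaks[-1]])          # highest-VAF cluster
    # the raw KDE mode is biased by depth heterogeneity and binomial skew;
    # recentre on the cluster with a few mean-shift steps
    for _ in range(5):
        near = vafs[np.abs(vafs - mode) <= 0.06]
        if near.size == 0:
            break
        new = float(near.mean())
        if abs(new - mode) < 1e-4:
            mode = new
            break
        mode = new
    rho = 2.0 * mode
    clamped = not (0.05 <= rho <= 1.0)
    rho = float(np.clip(rho, 0.05, 1.0))
    return PurityEstimate(sample=sample, rho=rho, method="from_vaf",
                          mode_vaf=mode, clamped=clamped)


def copy_neutral_vafs(variants: MultiRegionVariantSet, segments: SegmentProfile,
                      sample: str, min_depth: int = 10) -> np.ndarray:
    """VAFs of SNVs lying in diploid heterozygous (1+1) segments of ``sample``."""
    chroms = variants.variants["chrom"].to_numpy()
    poss = variants.variants["pos"].to_numpy()
    alt = variants.alt_counts[sample].to_numpy(dtype=float)
    depth = variants.depth[sample].to_numpy(dtype=float)
    keep = []
    for i in range(variants.n_variants):
        if depth[i] < min_depth or alt[i] == 0:
            continue
        seg = segments.locate(sample, chroms[i], int(poss[i]))
        if seg is not None and seg["major"] == 1 and seg["minor"] == 1:
            keep.append(alt[i] / depth[i])
    return np.asarray(keep)


# ---------------------------------------------------------------------------
# Dirichlet-process clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterSet:
    """Mutation clusters with per-sample CCF centroids."""

    centroids: np.ndarray            # K x S
    assignment: np.ndarray           # cluster index per mutation
    samples: list[str]
    sizes: np.ndarray = None
    density: tuple | None = None     # (grid axis, smoothed density array), S <= 3
    converged: bool = True
    k_trace: np.ndarray | None = None
    mutation_index: pd.Index | None = None
    # raw data retained for reassignment in filter_clusters
    _alt: np.ndarray | None = field(default=None, repr=False)
    _depth: np.ndarray | None = field(default=None, repr=False)
    _coef: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.sizes is None:
            self.sizes = np.bincount(self.assignment, minlength=len(self.centroids))

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def n_mutations(self) -> int:
        return len(self.assignment)

    def centroid_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.centroids, columns=self.samples)


def _binom_loglik(alt: np.ndarray, depth: np.ndarray, coef: np.ndarray,
                  phi: np.ndarray) -> np.ndarray:
    """Log-likelihood of each mutation under each candidate CCF vector.

    alt, depth, coef: n x S; phi: K x S -> returns n x K.
    """
    v = coef[:, None, :] * phi[None, :, :]
    v = np.clip(v, 1e-12, 1.0 - 1e-12)
    db = depth - alt
    return (alt[:, None, :] * np.log(v) + db[:, None, :] * np.log1p(-v)).sum(axis=2)


def _canonical_order(alt, depth, coef) -> np.ndarray:
    """Data-determined total order, so results are invariant to the input
    permutation (identical rows are interchangeable)."""
    keys = np.hstack([alt, depth, np.round(coef, 12)])
    return np.lexsort(keys.T[::-1])


def dp_cluster(alt, depth, coef, *, n_iter: int = 2000, burn_in: int = 1000,
               k_max: int = 30, seed: int = 0, grid_step: float = 0.02,
               phi_max: float = CCF_CLAMP, merge_radius: float = 0.1,
               min_basin_fraction: float = 0.005,
               samples: Sequence[str] | None = None,
               mutation_index: pd.Index | None = None) -> ClusterSet:
    """Multi-sample mutation clustering via a truncated stick-breaking
    Dirichlet process with binomial read-count emissions.

    Cluster CCFs are Gibbs-sampled on a per-sample grid (step ``grid_step``
    up to ``phi_max``); the DP concentration is resampled each sweep under a
    Gamma(1,1) prior. After burn-in, each mutation's posterior-mean CCF
    vector is accumulated; clone clusters are the local peaks of the
    smoothed posterior mutation density (full S-dimensional grid for
    S <= 3, mode-merging of posterior-mean vectors above), and each mutation
    is assigned to the basin of the peak under which its read counts are
    most likely. Deterministic given ``seed``.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    coef = np.asarray(coef, dtype=float)
    if alt.ndim == 1:
        alt, depth, coef = alt[:, None], depth[:, None], coef[:, None]
    n, S = alt.shape
    if n < 50:
        raise InsufficientDataError(f"need >= 50 mutations for DP clustering, got {n}")
    if samples is None:
        samples = [f"S{j}" for j in range(S)]

    order = _canonical_order(alt, depth, coef)
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    b = alt[order]
    d = depth[order]
    c = coef[order]
    db = d - b

    rng = np.random.default_rng(seed)
    grid = np.round(np.arange(0.0, phi_max + grid_step / 2, grid_step), 10)
    G = len(grid)

    z = rng.integers(0, k_max, size=n)
    phi = rng.uniform(0.0, 1.0, size=(k_max, S))
    alpha = 1.0
    phi_sum = np.zeros((n, S))
    n_keep = 0
    k_trace = []

    for it in range(n_iter):
        # --- phi | z : grid Gibbs per occupied cluster ---
        sort_idx = np.argsort(z, kind="stable")
        counts = np.bincount(z, minlength=k_max)
        bounds = np.r_[0, np.cumsum(counts)]
        gum = rng.gumbel(size=(k_max, G, S))
        for k in range(k_max):
            lo, hi = bounds[k], bounds[k + 1]
            if hi == lo:
                phi[k] = grid[rng.integers(0, G, size=S)]
                continue
            mem = sort_idx[lo:hi]
            cm = c[mem]                                   # nk x S
            v = cm[:, :, None] * grid[None, None, :]      # nk x S x G
            v = np.clip(v, 1e-12, 1.0 - 1e-12)
            ll = (b[mem][:, :, None] * np.log(v)
                  + db[mem][:, :, None] * np.log1p(-v)).sum(axis=0)  # S x G
            phi[k] = grid[np.argmax(ll.T + gum[k], axis=0)]

        # --- stick weights + concentration ---
        tail = counts[::-1].cumsum()[::-1] - counts
        vbeta = rng.beta(1.0 + counts[:-1], alpha + tail[:-1])
        vbeta = np.clip(vbeta, 1e-12, 1.0 - 1e-12)
        logw = np.empty(k_max)
        logw[:-1] = np.log(vbeta)
        log1mv = np.log1p(-vbeta)
        logw[1:] += np.cumsum(log1mv)
        alpha = rng.gamma(1.0 + k_max - 1, 1.0 / (1.0 - log1mv.sum()))

        # --- z | phi ---
        logp = _binom_loglik(b, d, c, phi) + logw[None, :]
        z = np.argmax(logp + rng.gumbel(size=(n, k_max)), axis=1)

        if it >= burn_in:
            phi_sum += phi[z]
            n_keep += 1
            k_trace.append(len(np.unique(z)))

    phi_mean = phi_sum / max(n_keep, 1)

    # --- peak finding on the posterior mutation density ---
    if S <= 3:
        cells = np.clip(np.rint(phi_mean / grid_step).astype(int), 0, G - 1)
        hist = np.zeros((G,) * S)
        np.add.at(hist, tuple(cells.T), 1.0)
        dens = ndimage.gaussian_filter(hist, sigma=1.0, mode="constant")
        local_max = (ndimage.maximum_filter(dens, size=3, mode="constant") == dens)
        peak_cells = np.argwhere(local_max & (dens > 0))
        peak_phi = peak_cells.astype(float) * grid_step
        peak_mass = dens[tuple(peak_cells.T)]
        density = (grid, dens)
    else:
        cells = np.clip(np.rint(phi_mean / grid_step).astype(int), 0, G - 1)
        uniq, counts_u = np.unique(cells, axis=0, return_counts=True)
        keep = np.argsort(-counts_u, kind="stable")
        peak_phi = uniq[keep].astype(float) * grid_step
        peak_mass = counts_u[keep].astype(float)
        density = None

    # merge nearby peaks (descending mass), then basin assignment
    order_m = np.argsort(-peak_mass, kind="stable")
    kept: list[int] = []
    for i in order_m:
        if all(np.abs(peak_phi[i] - peak_phi[j]).max() > merge_radius for j in kept):
            kept.append(i)
    peak_phi = peak_phi[kept]
    peak_mass = peak_mass[kept]

    def _assign(peaks):
        ll = _binom_loglik(b, d, c, peaks)
        return np.argmax(ll, axis=1)

    assign = _assign(peak_phi)
    # prune basins holding less than min_basin_fraction of mutations
    min_n = max(1, int(np.floor(min_basin_fraction * n)))
    while True:
        sizes = np.bincount(assign, minlength=len(peak_phi))
        small = [i for i in range(len(peak_phi)) if sizes[i] < min_n]
        if len(small) == 0 or len(peak_phi) - len(small) < 1:
            break
        keep_mask = np.ones(len(peak_phi), dtype=bool)
        keep_mask[small] = False
        peak_phi = peak_phi[keep_mask]
        peak_mass = peak_mass[keep_mask]
        assign = _assign(peak_phi)

    # BIC-guided consolidation: a finite chain fragments true clusters into
    # adjacent minor modes that memorise binomial noise. Merge a pair of
    # components whenever the soft-mixture log-likelihood gain of keeping
    # them separate is below the BIC cost of the extra component (its S-dim
    # CCF vector plus a mixing weight). Centroids are count-based MLEs so
    # the test sees the data, not the chain's label history.
    members = [np.flatnonzero(assign == i) for i in range(len(peak_phi))]
    members = [m for m in members if m.size > 0]
    penalty = 0.5 * (S + 1) * np.log(max(n, 2))

    def _centroid(idx: np.ndarray) -> np.ndarray:
        # ratio estimator solving the binomial score equation (exact for
        # constant coefficients)
        num = b[idx].sum(axis=0)
        den = (d[idx] * c[idx]).sum(axis=0)
        return np.clip(np.where(den > 0, num / np.maximum(den, 1e-12), 0.0),
                       0.0, phi_max)

    def _mixture_loglik(cents: np.ndarray, weights: np.ndarray) -> float:
        ll = _binom_loglik(b, d, c, cents) + np.log(weights)[None, :]
        m = ll.max(axis=1)
        return float((m + np.log(np.exp(ll - m[:, None]).sum(axis=1))).sum())

    while len(members) > 1:
        cents = np.array([_centroid(m) for m in members])
        weights = np.array([len(m) for m in members], dtype=float)
        weights /= weights.sum()
        ll_cur = _mixture_loglik(cents, weights)
        best = None
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pooled = np.concatenate([members[i], members[j]])
                cents_m = np.vstack([cents[[k for k in range(len(members))
                                            if k not in (i, j)]],
                                     _centroid(pooled)[None, :]])
                w_m = np.r_[weights[[k for k in range(len(members))
                                     if k not in (i, j)]],
                            weights[i] + weights[j]]
                delta = ll_cur - _mixture_loglik(cents_m, w_m)
                if best is None or delta < best[0]:
                    best = (delta, i, j)
        if best[0] >= penalty:
            break
        _, i, j = best
        members[i] = np.concatenate([members[i], members[j]])
        del members[j]

    # final basins against consolidated centroids
    centroids = np.array([_centroid(m) for m in members])
    assign = _assign(centroids)
    sizes = np.bincount(assign, minlength=len(centroids))
    nonempty = np.flatnonzero(sizes > 0)
    remap = -np.ones(len(centroids), dtype=int)
    remap[nonempty] = np.arange(len(nonempty))
    assign = remap[assign]
    centroids = np.array([
        _centroid(np.flatnonzero(assign == kk)) for kk in range(len(nonempty))
    ])

    k_trace = np.asarray(k_trace)
    if len(k_trace):
        tail = k_trace[len(k_trace) // 2:]
        vals, cnts = np.unique(tail, return_counts=True)
        mode = vals[int(np.argmax(cnts))]
        # occupied-component counts jitter by a couple of singleton sticks;
        # call the chain stable when the mode +-2 band holds most draws
        converged = (np.abs(tail - mode) <= 2).mean() >= 0.6
    else:
        converged = False
    if not converged:
        log.warning("DP chain did not stabilise its cluster count; results flagged")

    return ClusterSet(
        centroids=centroids, assignment=assign[inv], samples=list(samples),
        density=density, converged=bool(converged), k_trace=k_trace,
        mutation_index=mutation_index,
        _alt=alt, _depth=depth, _coef=coef,
    )


def cluster_variants(variants: MultiRegionVariantSet, segments: SegmentProfile,
                     purity: Mapping[str, float], include_indels: bool = False,
                     **dp_kwargs) -> tuple[ClusterSet, CCFEstimate]:
    """End-to-end clustering from a variant set: CCF table then DP."""
    keep = variants.variants["var_class"] == "SNV"
    if include_indels:
        keep = keep | (variants.variants["var_class"] == "indel")
    sub = MultiRegionVariantSet(
        variants.variants[keep].reset_index(drop=True),
        variants.ref_counts[keep].reset_index(drop=True),
        variants.alt_counts[keep].reset_index(drop=True),
    )
    est = compute_ccf_matrix(sub, segments, purity)
    usable = ~sub.variants.index.isin(est.excluded)
    samples = est.samples
    clusters = dp_cluster(
        sub.alt_counts.loc[usable, samples].to_numpy(),
        sub.depth.loc[usable, samples].to_numpy(),
        est.coef.loc[usable].to_numpy(),
        samples=samples,
        mutation_index=sub.variants.index[usable],
        **dp_kwargs,
    )
    return clusters, est


# ---------------------------------------------------------------------------
# cluster-removal rules
# ---------------------------------------------------------------------------

def _centroid_se(clusters: ClusterSet) -> np.ndarray:
    """Approximate binomial standard error of each centroid (K x S)."""
    se = np.zeros_like(clusters.centroids)
    for k in range(clusters.n_clusters):
        mem = clusters.assignment == k
        nk = mem.sum()
        if nk == 0 or clusters._depth is None:
            continue
        d = clusters._depth[mem]
        cf = np.maximum(clusters._coef[mem], 1e-6)
        v = np.clip(cf * clusters.centroids[k][None, :], 1e-6, 1 - 1e-6)
        var_phi = v * (1 - v) / np.maximum(d, 1.0) / cf**2
        se[k] = np.sqrt(var_phi.mean(axis=0) / nk)
    return se


def filter_clusters(clusters: ClusterSet, chrom: Sequence | None = None, *,
                    min_fraction: float = 0.01, chrom_fraction: float = 0.5,
                    max_chromosomes: int = 2, min_cluster_size: int = 20,
                    tolerance: float | None = None) -> tuple[ClusterSet, list[dict]]:
    """Apply the three cluster-removal rules and reassign freed mutations.

    1. cluster holds < ``min_fraction`` of all mutations;
    2. most mutations (>= ``chrom_fraction``) localize to <=
       ``max_chromosomes`` chromosomes (only for clusters of at least
       ``min_cluster_size`` mutations);
    3. pigeonhole conflict: the cluster's centroid exceeds the truncal
       cluster's in some sample beyond a depth-aware tolerance
       eps = max(0.05, 2 x binomial SE).

    Returns the pruned cluster set and an audit log of removals.
    """
    n = clusters.n_mutations
    k = clusters.n_clusters
    audit: list[dict] = []
    remove = np.zeros(k, dtype=bool)

    # truncal cluster: closest to CCF 1 in every sample (a super-clonal
    # artifact cluster must not be mistaken for the trunk)
    trunk = int(np.argmin(np.abs(clusters.centroids - 1.0).mean(axis=1)))
    se = _centroid_se(clusters)
    eps = np.maximum(0.05, 2.0 * se) if tolerance is None else np.full_like(se, tolerance)

    chrom_arr = np.asarray(chrom) if chrom is not None else None
    for kk in range(k):
        size = int(clusters.sizes[kk])
        if size < min_fraction * n:
            remove[kk] = True
            audit.append({"cluster": kk, "rule": 1,
                          "detail": f"{size}/{n} mutations (< {min_fraction:.0%})"})
            continue
        if chrom_arr is not None and size >= min_cluster_size:
            mem_chroms = chrom_arr[clusters.assignment == kk]
            top = pd.Series(mem_chroms).value_counts().iloc[:max_chromosomes].sum()
            if top >= chrom_fraction * size:
                remove[kk] = True
                audit.append({"cluster": kk, "rule": 2,
                              "detail": f"{top}/{size} mutations on <= "
                                        f"{max_chromosomes} chromosomes"})
                continue
        if kk != trunk:
            excess = clusters.centroids[kk] - clusters.centroids[trunk] - eps[kk]
            if np.any(excess > 0):
                s = int(np.argmax(excess))
                remove[kk] = True
                audit.append({"cluster": kk, "rule": 3,
                              "detail": f"centroid {clusters.centroids[kk, s]:.3f} "
                                        f"exceeds trunk in sample {clusters.samples[s]}"})

    if remove.all():
        raise PipelineError("all clusters removed: degenerate clustering")
    if not remove.any():
        return clusters, audit

    survivors = np.flatnonzero(~remove)
    remap = -np.ones(k, dtype=int)
    remap[survivors] = np.arange(len(survivors))
    new_assign = remap[clusters.assignment]
    freed = new_assign < 0
    if freed.any() and clusters._alt is not None:
        ll = _binom_loglik(clusters._alt[freed], clusters._depth[freed],
                           clusters._coef[freed], clusters.centroids[survivors])
        new_assign[freed] = np.argmax(ll, axis=1)
    elif freed.any():
        # fall back to nearest centroid when raw counts are unavailable
        new_assign[freed] = 0

    for entry in audit:
        log.info("removed cluster %d under rule %d: %s",
                 entry["cluster"], entry["rule"], entry["detail"])

    return ClusterSet(
        centroids=clusters.centroids[survivors],
        assignment=new_assign, samples=clusters.samples,
        density=clusters.density, converged=clusters.converged,
        k_trace=clusters.k_trace, mutation_index=clusters.mutation_index,
        _alt=clusters._alt, _depth=clusters._depth, _coef=clusters._coef,
    ), audit
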