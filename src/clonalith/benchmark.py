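"""Well-posed benchmark tumors for validating the reconstruction pipeline.

Recovery experiments only measure algorithm correctness when the target is
recoverable from the data at all. Two ingredients make a simulated tumor a
fair benchmark:

* separation — all cluster CCF vectors at least ``min_gap`` apart
  (max-norm), so clusters are distinguishable at the simulated depth;
* identifiability — the true tree is the unique optimum of the constraint
  score at the noise-free CCFs. CCF-based tree inference fundamentally
  cannot distinguish, e.g., a chain from siblings when both satisfy every
  constraint; such configurations measure tie-break luck, not correctness,
  and are rejection-sampled away here.

Purity defaults to 0.7, the histological inclusion floor of multi-region
study designs (samples must exceed 70% tumor nuclei).
"""

from __future__ import annotations

import numpy as np

from .errors import SimulationError
from .io import MultiRegionVariantSet, SegmentProfile
from .phylo import build_tree
from .simulate import (
    GroundTruth, SimConfig, simulate_reads, simulate_scnas, simulate_tree,
)


def benchmark_tree(seed: int, n_regions: int = 3, n_clusters: int = 4,
                   mutations_per_cluster: int = 150, purity: float = 0.7,
                   min_gap: float = 0.2, tolerance: float = 0.05,
                   max_tries: int = 300, **config_kwargs) -> tuple[SimConfig, GroundTruth]:
    """A separated, identifiable ground-truth tree (no reads yet)."""
    for attempt in range(max_tries):
        cfg = SimConfig(n_regions=n_regions, n_clusters=n_clusters,
                        mutations_per_cluster=mutations_per_cluster,
                        purity_per_region=purity, seed=seed, **config_kwargs)
        rng = np.random.default_rng([seed, attempt])
        try:
            truth = simulate_tree(cfg, rng, min_gap=min_gap)
        except SimulationError:
            continue
        tree = build_tree(truth.cluster_ccf, tolerance=tolerance)
        if np.array_equal(tree.parent, truth.parent):
            return cfg, truth
    raise SimulationError(
        f"no identifiable configuration found in {max_tries} tries (seed {seed})")


def benchmark_tumor(seed: int, **kwargs) -> tuple[
        SimConfig, GroundTruth, SegmentProfile, MultiRegionVariantSet]:
    """Identifiable benchmark tumor with segments and simulated reads."""
    cfg, truth = benchmark_tree(seed, **kwargs)
    rng = np.random.default_rng([seed, 9999])
    segments = simulate_scnas(truth, cfg, rng)
    variants = simulate_reads(truth, cfg, segments, rng)
    return cfg, truth, segments, variants


# ---------------------------------------------------------------------------
# validation experiments (shared by the test suite and the acceptance script)
# ---------------------------------------------------------------------------

def recovery_experiment(n_tumors: int = 20, seed: int = 0,
                        n_iter: int = 2000, burn_in: int = 1000) -> list[dict]:
    """Full-pipeline recovery on identifiable benchmark tumors: cluster
    count, matched-centroid MAE, tree parent vector, and the violation of
    the returned tree vs the truth scored on the estimated centroids."""
    from scipy.optimize import linear_sum_assignment

    from .inference import cluster_variants, filter_clusters
    from .phylo import tree_violation

    out = []
    for i in range(n_tumors):
        cfg, truth, segments, variants = benchmark_tumor(seed * 1009 + i)
        purity = dict(zip(truth.region_names, truth.purity))
        clusters, _ = cluster_variants(variants, segments, purity,
                                       seed=seed * 13 + i, n_iter=n_iter,
                                       burn_in=burn_in)
        clusters, _ = filter_clusters(
            clusters, variants.variants.loc[clusters.mutation_index, "chrom"])
        rec = {"k_true": truth.n_clusters, "k_est": clusters.n_clusters,
               "mae": None, "tree_match": False, "never_worse": True,
               "est_ccf": clusters.centroids, "true_ccf": truth.cluster_ccf,
               "est_parent": None, "true_parent": truth.parent}
        if clusters.n_clusters == truth.n_clusters:
            cost = np.abs(clusters.centroids[:, None, :]
                          - truth.cluster_ccf[None, :, :]).mean(axis=2)
            r, c = linear_sum_assignment(cost)
            rec["mae"] = float(cost[r, c].mean())
            to_true = dict(zip(r.tolist(), c.tolist()))
            to_est = {v: k for k, v in to_true.items()}
            tree = build_tree(clusters)
            rec["est_parent"] = tree.parent
            est_in_true = [-1 if tree.parent[to_est[t]] < 0
                           else to_true[tree.parent[to_est[t]]]
                           for t in range(truth.n_clusters)]
            rec["tree_match"] = est_in_true == truth.parent.tolist()
            truth_as_est = np.array([-1 if truth.parent[to_true[e]] < 0
                                     else to_est[truth.parent[to_true[e]]]
                                     for e in range(truth.n_clusters)])
            truth_score = tree_violation(truth_as_est, clusters.centroids, 0.05)
            rec["never_worse"] = tree.violation <= truth_score + 1e-9
        out.append(rec)
    return out


def random_feasible_trees(n: int = 1000, seed: int = 0):
    """Pigeonhole-consistent CCF matrices (random K, 3 regions) and the tree
    the package builds for each; the caller applies its own checker."""
    for i in range(n):
        k = 2 + (seed + i) % 5
        cfg = SimConfig(n_regions=3, n_clusters=k, seed=seed * 2003 + i)
        truth = simulate_tree(cfg)
        tree = build_tree(truth.cluster_ccf)
        yield truth.cluster_ccf, tree


def timing_experiment(seed: int = 0, n_info: int = 200, reps: int = 20) -> dict:
    """Gain-time recovery from constant-rate accrual draws at
    t in {0.1, ..., 0.9} for both gain types."""
    from .phylo import time_gain

    rng = np.random.default_rng(seed)
    maes = {}
    for gain_type in ("2+1", "2+0"):
        errs = []
        for t in np.arange(0.1, 0.95, 0.1):
            p2 = t / (3 - t) if gain_type == "2+1" else t / (2 - t)
            for _ in range(reps):
                n2 = rng.binomial(n_info, p2)
                est = time_gain(n1=n_info - n2, n2=int(n2), gain_type=gain_type)
                errs.append(abs(est.t - t))
        maes[gain_type] = float(np.mean(errs))
    return maes


def apith_experiment(n_tumors: int = 100, seed: int = 0,
                     n_regions: int = 6, n_sub: int = 4) -> dict:
    """Mean APITH under the base region count, random subsampling, and a
    doubled region count on the same trees."""
    from .metrics import apith, presence_matrix
    from .simulate import extend_regions

    base_v, sub_v, dbl_v = [], [], []
    for i in range(n_tumors):
        s = seed * 4001 + i
        cfg = SimConfig(n_regions=n_regions, n_clusters=5, n_mutations=600, seed=s)
        rng = np.random.default_rng(s)
        truth = simulate_tree(cfg, rng)
        truth2 = extend_regions(truth, cfg, n_regions, rng)
        variants = simulate_reads(truth2, cfg, None, rng, include_normal=False)
        pres = presence_matrix(variants)
        base = truth2.region_names[:n_regions]
        base_v.append(apith(pres, base))
        subs = [apith(pres, [base[j] for j in
                             np.sort(rng.choice(n_regions, n_sub, replace=False))])
                for _ in range(5)]
        sub_v.append(float(np.mean(subs)))
        dbl_v.append(apith(pres, truth2.region_names))
    b = float(np.mean(base_v))
    return {
        "base": b,
        "subsampled": float(np.mean(sub_v)),
        "doubled": float(np.mean(dbl_v)),
        "subsample_shift_pct": 100 * abs(np.mean(sub_v) - b) / b,
        "double_shift_pct": 100 * abs(np.mean(dbl_v) - b) / b,
    }


def congruence_experiment(signal_fraction: float, n_seeds: int = 100,
                          seed: int = 0, n_tumors: int = 14,
                          n_regions: int = 6) -> np.ndarray:
    """Cohort congruence rho per seed: pairwise subclonal-SNV vs methylation
    distances pooled over ``n_tumors`` simulated tumors."""
    import pandas as pd

    from .metrics import congruence_from_pairs, congruence_pairs, presence_matrix
    from .simulate import simulate_methylation

    rhos = []
    for s in range(n_seeds):
        pairs = []
        for t in range(n_tumors):
            ts = seed * 7_000_003 + s * 1000 + t
            cfg = SimConfig(n_regions=n_regions, n_clusters=5, n_mutations=400,
                            n_probes=8000, meth_signal_fraction=signal_fraction,
                            seed=ts)
            rng = np.random.default_rng(ts)
            truth = simulate_tree(cfg, rng)
            variants = simulate_reads(truth, cfg, None, rng, include_normal=False)
            beta = simulate_methylation(truth, cfg, rng)
            pres = presence_matrix(variants)
            pairs.append(congruence_pairs(pres, truth.mutation_cluster == 0,
                                          beta, truth.region_names))
        allp = pd.concat(pairs, ignore_index=True)
        rhos.append(congruence_from_pairs(allp["snv_distance"],
                                          allp["beta_distance"]).rho)
    return np.asarray(rhos)
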