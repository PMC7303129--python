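"""Generator contracts: pigeonhole by construction, forward VAF model,
SCNA clonality structure, methylation bounds, determinism."""

import numpy as np
import pandas as pd
import pytest

from clonalith.errors import ConfigError
from clonalith.model import expected_vaf
from clonalith.simulate import (
    SimConfig, simulate_methylation, simulate_reads, simulate_scnas,
    simulate_svs, simulate_tree, simulate_tumor,
)


def independent_pigeonhole_check(parent, ccf, tol=1e-9):
    """Brute-force constraint check, written independently of GroundTruth."""
    k, n_regions = ccf.shape
    if not np.all(np.abs(ccf[0] - 1.0) <= tol):
        return False
    for r in range(n_regions):
        for p in range(k):
            total = 0.0
            for c in range(1, k):
                if parent[c] == p:
                    total += ccf[c, r]
                    if ccf[c, r] > ccf[p, r] + tol:
                        return False
            if total > ccf[p, r] + tol:
                return False
    return True


class TestTree:
    def test_single_cluster_is_clonal_everywhere(self):
        truth = simulate_tree(SimConfig(n_clusters=1, n_regions=3, seed=0))
        assert truth.cluster_ccf.shape == (1, 3)
        assert np.allclose(truth.cluster_ccf, 1.0)

    def test_invalid_cluster_count_rejected(self):
        with pytest.raises(ConfigError):
            simulate_tree(SimConfig(n_clusters=0, seed=0))

    def test_pigeonhole_by_construction(self):
        truth = simulate_tree(SimConfig(n_clusters=3, n_regions=2, seed=7))
        ccf = truth.cluster_ccf
        for c in range(1, 3):
            assert np.all(ccf[c] <= ccf[truth.parent[c]] + 1e-9)

    @pytest.mark.parametrize("seed_block", [0, 1])
    def test_many_draws_pass_independent_checker(self, seed_block):
        """1,000 generated trees all satisfy an independent pigeonhole
        checker (split in two blocks of 500)."""
        for s in range(500):
            seed = seed_block * 500 + s
            truth = simulate_tree(SimConfig(n_clusters=5, n_regions=3, seed=seed))
            assert independent_pigeonhole_check(truth.parent, truth.cluster_ccf)

    def test_region_restricted_cluster_exists(self):
        for seed in range(20):
            truth = simulate_tree(SimConfig(n_clusters=5, n_regions=4, seed=seed))
            present = truth.cluster_ccf > 0
            assert np.any(present[1:].sum(axis=1) == 1)

    def test_intermixing_guarantee(self):
        for seed in range(20):
            truth = simulate_tree(SimConfig(n_clusters=5, n_regions=4,
                                            intermix_prob=0.5, seed=seed))
            ccf = truth.cluster_ccf
            found = False
            for c in range(1, truth.n_clusters):
                parent_ccf = ccf[truth.parent[c]]
                regs = np.flatnonzero((ccf[c] > 1e-9) & (ccf[c] < parent_ccf - 1e-9))
                if regs.size >= 2 and regs.max() - regs.min() >= 2:
                    found = True
            assert found

    def test_every_cluster_present_somewhere(self):
        for seed in range(30):
            truth = simulate_tree(SimConfig(n_clusters=6, n_regions=3, seed=seed))
            assert np.all((truth.cluster_ccf > 0).any(axis=1))


class TestReads:
    def test_clonal_diploid_vaf(self):
        """phi=1, rho=0.5, CN=2, mult=1 -> mean VAF 0.25 within 0.005."""
        cfg = SimConfig(n_clusters=1, n_regions=1, n_mutations=10000,
                        purity_per_region=0.5, seed=1)
        truth = simulate_tree(cfg)
        variants = simulate_reads(truth, cfg, None, include_normal=False)
        vaf = variants.vaf.to_numpy()
        assert abs(vaf.mean() - 0.25) < 0.005

    def test_absent_mutation_has_zero_alt(self):
        cfg = SimConfig(n_clusters=2, n_regions=2, n_mutations=200, seed=2,
                        purity_per_region=0.6)
        truth = simulate_tree(cfg)
        truth.cluster_ccf[1, :] = 0.0
        variants = simulate_reads(truth, cfg, None, include_normal=False)
        absent = truth.mutation_cluster == 1
        assert variants.alt_counts.to_numpy()[absent].sum() == 0

    def test_forward_equation_grid(self):
        """Empirical VAF means match the forward equation within 3 SE on a
        (phi, rho, CN, mult) grid."""
        rng = np.random.default_rng(0)
        n, depth_mean = 3000, 60
        for phi in (0.2, 0.5, 0.8, 1.0):
            for rho in (0.3, 0.5, 0.7, 0.9):
                for cn, mult in ((2, 1), (2, 2), (3, 1), (3, 2), (1, 1), (4, 2)):
                    v = float(expected_vaf(phi, rho, cn, mult))
                    if v > 1:
                        continue
                    depth = rng.poisson(depth_mean, n)
                    alt = rng.binomial(depth, v)
                    vaf = alt / np.maximum(depth, 1)
                    se = np.sqrt(max(v * (1 - v), 1e-6) / depth_mean / n)
                    assert abs(vaf.mean() - v) < 3.5 * se + 1e-3

    def test_derived_case_subclonal_high_purity(self):
        """phi=0.5, rho=0.8, CN=3, mult=1 -> VAF 1/7 within 0.005."""
        cfg = SimConfig(n_clusters=2, n_regions=1, seed=3,
                        mutations_per_cluster=[100, 10000], purity_per_region=0.8)
        truth = simulate_tree(cfg)
        truth.cluster_ccf[1, :] = 0.5
        segments = simulate_scnas(truth, cfg)
        # force a whole-genome 2+1 state so every locus is CN 3
        df = segments.df.copy()
        df.loc[:, ["total", "major", "minor", "state"]] = [3, 2, 1, "ASCNA"]
        from clonalith.io import SegmentProfile
        truth.scna_events = None
        variants = simulate_reads(truth, cfg, SegmentProfile(df), include_normal=False)
        sub = truth.mutation_cluster == 1
        vaf = variants.vaf.to_numpy()[sub]
        expected = 0.5 * 0.8 / (0.8 * 3 + 0.4)
        assert abs(expected - 1 / 7) < 1e-12
        assert abs(vaf.mean() - expected) < 0.005


class TestScnas:
    def test_no_focal_means_all_clonal(self):
        cfg = SimConfig(n_focal_scnas=0, seed=1)
        truth = simulate_tree(cfg)
        simulate_scnas(truth, cfg)
        assert set(truth.scna_clonality) == {"clonal"}

    def test_focal_restricted_to_subsets(self):
        cfg = SimConfig(n_arm_scnas=0, n_focal_scnas=3, n_regions=3, seed=2)
        truth = simulate_tree(cfg)
        simulate_scnas(truth, cfg)
        ev = truth.scna_events
        assert set(ev["clonality"]) == {"subclonal"}
        assert all(len(r) < 3 for r in ev["regions"])

    def test_clonal_events_larger_than_focal(self):
        """Median clonal (arm) size exceeds median subclonal (focal) size in
        at least 95 of 100 seeds."""
        wins = 0
        for seed in range(100):
            cfg = SimConfig(seed=seed)
            truth = simulate_tree(cfg)
            simulate_scnas(truth, cfg)
            ev = truth.scna_events
            ev = ev.assign(size=ev["end"] - ev["start"] + 1)
            med = ev.groupby("clonality")["size"].median()
            if "clonal" in med and "subclonal" in med and med["clonal"] > med["subclonal"]:
                wins += 1
        assert wins >= 95

    def test_segments_valid_profile(self, small_bundle):
        bundle, _ = small_bundle
        bundle.segments.validate()  # no overlaps, totals consistent


class TestMethylation:
    def test_betas_bounded(self):
        for seed in (0, 5):
            cfg = SimConfig(n_probes=500, seed=seed)
            truth = simulate_tree(cfg)
            beta = simulate_methylation(truth, cfg)
            v = beta.values.to_numpy()
            assert v.min() >= 0.0 and v.max() <= 1.0

    def test_probe_floor_enforced(self):
        with pytest.raises(ConfigError):
            cfg = SimConfig(n_probes=50, seed=0)
            simulate_methylation(simulate_tree(SimConfig(seed=0)), cfg)

    def test_normals_lack_subclone_signal(self):
        cfg = SimConfig(n_probes=2000, meth_signal_fraction=1.0,
                        meth_noise_sd=0.0, seed=4)
        truth = simulate_tree(cfg)
        beta = simulate_methylation(truth, cfg)
        # without noise, the normal column equals the baseline everywhere
        tumor_sd = beta.values[truth.region_names].std(axis=1)
        assert (tumor_sd > 0).sum() > 0
        assert beta.values["N01"].between(0, 1).all()


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        from clonalith.simulate import simulate_to_dir
        cfg = SimConfig(n_mutations=150, n_probes=300, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_to_dir(cfg, d1, seed=9)
        simulate_to_dir(cfg, d2, seed=9)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_svs_deterministic_and_typed(self):
        cfg = SimConfig(n_svs=25, seed=6)
        truth = simulate_tree(cfg)
        svs1 = simulate_svs(truth, cfg)
        svs2 = simulate_svs(truth, cfg)
        pd.testing.assert_frame_equal(svs1.events, svs2.events)
        intra = svs1.events["chrom1"] == svs1.events["chrom2"]
        assert (svs1.events.loc[intra, "size"] > 0).all()
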