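"""ITH metrics: APITH, SCNA fractions and sizes, SV clonality, context ITH,
methylation variability/selection/clustering, congruence."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from clonalith.errors import UndefinedMetricError
from clonalith.io import BetaMatrix, SegmentProfile, SVSet
from clonalith.metrics import (
    apith, beta_distance, cluster_methylation, compare_scna_sizes,
    congruence_from_pairs, methylation_variability, presence_matrix,
    scna_clonal_fraction, scna_events, select_top_variable_probes,
    snv_distance, snv_ith_by_context, sv_clonality,
)


def _presence(d):
    return pd.DataFrame(d).astype(bool)


class TestApith:
    def test_identical_profiles_zero(self):
        p = _presence({"A": [1, 1, 0], "B": [1, 1, 0]})
        assert apith(p) == 0.0

    def test_hand_example(self):
        """A{m1,m2}, B{m1,m3}, C{m1}: distances 2,1,1 -> APITH = 4/3."""
        p = _presence({"A": [1, 1, 0], "B": [1, 0, 1], "C": [1, 0, 0]})
        assert apith(p) == pytest.approx(4 / 3)

    def test_needs_two_samples(self):
        with pytest.raises(UndefinedMetricError):
            apith(_presence({"A": [1, 0]}))

    def test_distance_matrix_properties(self, rng):
        p = pd.DataFrame(rng.random((50, 5)) < 0.5,
                         columns=list("ABCDE"))
        dm = snv_distance(p)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)


def _segments(rows):
    return SegmentProfile(pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "total", "major",
                       "minor", "frac", "state"]))


class TestScnaFractions:
    def test_shared_gain_is_clonal(self):
        rows = []
        for s in ("A", "B"):
            rows += [[s, "chr1", 1, 100, 3, 2, 1, 1.0, "ASCNA"],
                     [s, "chr1", 101, 1000, 2, 1, 1, 1.0, "HET"]]
        fr = scna_clonal_fraction(_segments(rows))
        assert fr["clonal_fraction"] == pytest.approx(0.1)
        assert fr["subclonal_fraction"] == 0.0

    def test_private_gain_is_subclonal(self):
        rows = [["A", "chr1", 1, 50, 3, 2, 1, 1.0, "ASCNA"],
                ["A", "chr1", 51, 1000, 2, 1, 1, 1.0, "HET"],
                ["B", "chr1", 1, 1000, 2, 1, 1, 1.0, "HET"]]
        fr = scna_clonal_fraction(_segments(rows))
        assert fr["subclonal_fraction"] == pytest.approx(0.05)
        assert fr["clonal_fraction"] == 0.0

    def test_nested_overlap_partition(self):
        """Arm gain everywhere plus an extra focal gain in one region: the
        focal interval is subclonal, the remainder of the arm clonal."""
        rows = [["A", "chr1", 1, 400, 3, 2, 1, 1.0, "ASCNA"],
                ["A", "chr1", 401, 1000, 2, 1, 1, 1.0, "HET"],
                ["B", "chr1", 1, 200, 3, 2, 1, 1.0, "ASCNA"],
                ["B", "chr1", 201, 300, 4, 3, 1, 1.0, "amp"],
                ["B", "chr1", 301, 400, 3, 2, 1, 1.0, "ASCNA"],
                ["B", "chr1", 401, 1000, 2, 1, 1, 1.0, "HET"]]
        fr = scna_clonal_fraction(_segments(rows))
        assert fr["clonal_fraction"] == pytest.approx(0.3)      # 1-200, 301-400
        assert fr["subclonal_fraction"] == pytest.approx(0.1)   # 201-300
        total = (fr["clonal_fraction"] + fr["subclonal_fraction"]
                 + fr["unaltered_fraction"])
        assert total == 1.0
        ev = scna_events(_segments(rows))
        assert set(ev["clonality"]) == {"clonal", "subclonal"}

    def test_single_region_rejected(self):
        rows = [["A", "chr1", 1, 100, 2, 1, 1, 1.0, "HET"]]
        with pytest.raises(UndefinedMetricError):
            scna_clonal_fraction(_segments(rows))


class TestScnaSizes:
    def test_extreme_separation_exact_p(self):
        """Clonal {10,20,30} vs subclonal {1,2,3}: the one-sided exact
        rank-sum p is 1/C(6,3) = 0.05."""
        stat, p = compare_scna_sizes([10e6, 20e6, 30e6], [1e6, 2e6, 3e6])
        assert p == pytest.approx(0.05)
        assert stat == 9.0  # maximum possible U

    def test_identical_groups_null(self):
        _, p = compare_scna_sizes([5, 6, 7, 8], [5, 6, 7, 8])
        assert p > 0.4

    def test_too_few_events(self):
        with pytest.raises(UndefinedMetricError):
            compare_scna_sizes([1, 2], [1, 2, 3])


class TestSvClonality:
    def _svs(self, presence_rows):
        n = len(presence_rows)
        events = pd.DataFrame({
            "chrom1": ["chr1"] * n, "pos1": np.arange(1, n + 1) * 1000,
            "chrom2": ["chr1"] * n, "pos2": np.arange(1, n + 1) * 1000 + 500,
            "sv_type": ["deletion"] * n, "size": [500] * n})
        presence = pd.DataFrame(presence_rows, columns=list("ABCD")).astype(bool)
        return SVSet(events, presence)

    def test_all_samples_clonal(self):
        out = sv_clonality(self._svs([[1, 1, 1, 1]]))
        assert out["labels"].iloc[0] == "clonal"

    def test_subset_subclonal(self):
        out = sv_clonality(self._svs([[1, 1, 0, 0]]))
        assert out["labels"].iloc[0] == "subclonal"

    def test_shared_fraction_forty_percent(self):
        rows = [[1, 1, 1, 1]] * 4 + [[1, 0, 0, 0]] * 6
        out = sv_clonality(self._svs(rows))
        assert out["shared_fraction"] == pytest.approx(0.40)
        assert out["clonal_count"] == 4 and out["subclonal_count"] == 6

    def test_zero_events_empty_summary(self):
        from clonalith.io import empty_svset
        out = sv_clonality(empty_svset(list("ABCD")))
        assert out["shared_fraction"] is None and out["clonal_count"] == 0


class TestContextIth:
    def test_all_truncal_zero(self):
        df = snv_ith_by_context(["promoters"] * 12, [True] * 12)
        assert df.loc[0, "nontruncal_fraction"] == 0.0
        assert not df.loc[0, "low_support"]

    def test_thirty_percent(self):
        df = snv_ith_by_context(["promoters"] * 10, [True] * 7 + [False] * 3)
        assert df.loc[0, "nontruncal_fraction"] == pytest.approx(0.3)

    def test_uniform_assignment_no_context_bias(self, rng):
        """With context-independent truncality, per-context fractions stay
        within 3 binomial SE of the global fraction (95% of seeds)."""
        contexts = np.array(["promoters", "introns", "exons", "intergenic"])
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            ctx = contexts[r.integers(0, 4, 800)]
            truncal = r.random(800) < 0.7
            df = snv_ith_by_context(ctx, truncal)
            g = 1 - truncal.mean()
            ok = True
            for _, row in df.iterrows():
                se = np.sqrt(g * (1 - g) / row["n"])
                if abs(row["nontruncal_fraction"] - g) > 3 * se:
                    ok = False
            hits += ok
        assert hits >= int(0.85 * n_seeds)


def _beta(values, contexts=None):
    idx = pd.Index([f"cg{i:07d}" for i in range(len(values))], name="probe")
    vals = pd.DataFrame(values, index=idx)
    vals.columns = [f"S{j}" for j in range(vals.shape[1])]
    ann = pd.DataFrame({
        "context": contexts if contexts is not None else ["exons"] * len(values),
        "cpg_island": False}, index=idx)
    return BetaMatrix(vals, ann)


class TestMethylation:
    def test_variability_hand_example(self):
        """Ranges {0.4, 0.2, 0.0} -> median 0.2."""
        beta = _beta([[0.1, 0.5], [0.2, 0.4], [0.3, 0.3]])
        out = methylation_variability(beta, ["S0", "S1"])
        assert out["exons"] == pytest.approx(0.2)

    def test_constant_probe_zero_range(self):
        beta = _beta([[0.5, 0.5]])
        assert methylation_variability(beta, ["S0", "S1"])["exons"] == 0.0

    def test_top_probe_selection_exact(self):
        vals = np.column_stack([np.linspace(0, 0.9, 100), np.zeros(100)])
        beta = _beta(vals)
        top = select_top_variable_probes(beta, 0.01, ["S0", "S1"])
        assert top == ["cg0000099"]

    def test_tie_breaks_lexicographic(self):
        vals = np.array([[0.9, 0.0], [0.9, 0.0], [0.1, 0.0]])
        beta = _beta(vals)
        top = select_top_variable_probes(beta, 1 / 3, ["S0", "S1"])
        assert top == ["cg0000000"]

    def test_selection_matches_full_sort_oracle(self, rng):
        vals = rng.random((1000, 4))
        beta = _beta(vals)
        got = select_top_variable_probes(beta, 0.05, [f"S{j}" for j in range(4)])
        ranges = vals.max(axis=1) - vals.min(axis=1)
        order = sorted(range(1000), key=lambda i: (-ranges[i], f"cg{i:07d}"))
        assert got == [f"cg{i:07d}" for i in order[:50]]

    def test_ward_linkage_matches_manual_recomputation(self, rng):
        """Linkage heights equal a brute-force Lance-Williams Ward update."""
        x = rng.random((6, 30))
        beta = _beta(x.T)
        mc = cluster_methylation(beta, samples=[f"S{j}" for j in range(6)])

        # naive Ward agglomeration oracle
        clusters = {i: [i] for i in range(6)}
        d = {(i, j): np.linalg.norm(x[i] - x[j]) ** 2
             for i in range(6) for j in range(i + 1, 6)}
        heights = []
        sizes = {i: 1 for i in range(6)}
        nxt = 6
        while len(clusters) > 1:
            (i, j), dij = min(d.items(), key=lambda kv: kv[1])
            heights.append(np.sqrt(dij))
            ni, nj = sizes[i], sizes[j]
            new = {}
            for (a, b), dab in d.items():
                if i in (a, b) or j in (a, b):
                    continue
                new[(a, b)] = dab
            for k in clusters:
                if k in (i, j):
                    continue
                nk = sizes[k]
                dik = d[tuple(sorted((i, k)))]
                djk = d[tuple(sorted((j, k)))]
                new[tuple(sorted((nxt, k)))] = (
                    (ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            clusters[nxt] = clusters.pop(i) + clusters.pop(j)
            sizes[nxt] = ni + nj
            d = new
            nxt += 1
        assert np.allclose(sorted(mc.linkage[:, 2]), sorted(heights), atol=1e-8)

    def test_two_blob_separation(self, rng):
        tumor = rng.normal(0.7, 0.02, (40, 4)).clip(0, 1)
        normal = rng.normal(0.2, 0.02, (40, 3)).clip(0, 1)
        beta = _beta(np.hstack([tumor, normal]))
        mc = cluster_methylation(beta, normal_samples=["S4", "S5", "S6"])
        assert mc.separation_score == 1.0
        flat = mc.flat_k2
        tumor_ids = [mc.samples.index(f"S{j}") for j in range(4)]
        assert len({flat[i] for i in tumor_ids}) == 1

    def test_low_purity_samples_cocluster(self):
        """Attenuated-signal (low purity) samples form their own group at
        k=3 in most seeds."""
        hits = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            sig = r.random(60)
            base = 0.3 + 0.0 * sig
            tumor = np.column_stack([(base + 0.4 * sig) for _ in range(3)])
            low = np.column_stack([(base + 0.4 * 0.3 * sig) for _ in range(2)])
            norm = np.column_stack([base for _ in range(2)])
            x = np.hstack([tumor, low, norm]) + r.normal(0, 0.02, (60, 7))
            beta = _beta(np.clip(x, 0, 1))
            mc = cluster_methylation(beta)
            flat3 = hierarchy.fcluster(mc.linkage, 3, criterion="maxclust")
            low_ids = [mc.samples.index(s) for s in ("S3", "S4")]
            others = [i for i in range(7) if i not in low_ids]
            grp = {flat3[i] for i in low_ids}
            hits += len(grp) == 1 and grp.isdisjoint({flat3[i] for i in others})
        assert hits >= 24


class TestCongruence:
    def test_perfect_monotone(self):
        snv = np.array([1, 2, 3, 4, 5, 6.0])
        beta = np.sqrt(snv)
        res = congruence_from_pairs(snv, beta)
        assert res.rho == 1.0

    def test_permutation_null_mean_zero(self, rng):
        rhos = []
        for _ in range(300):
            snv = rng.random(8)
            beta = rng.random(8)
            rhos.append(congruence_from_pairs(snv, beta).rho)
        assert abs(np.mean(rhos)) < 0.05

    def test_exact_p_matches_large_sample_direction(self):
        snv = np.arange(1, 8.0)
        beta = snv + 0.1
        res = congruence_from_pairs(snv, beta)
        assert res.rho == 1.0
        import math
        assert res.p_value == pytest.approx(2 / math.factorial(7), rel=1e-9)

    def test_invariant_to_monotone_rescaling(self, rng):
        snv = rng.random(12)
        beta = rng.random(12)
        r1 = congruence_from_pairs(snv, beta).rho
        r2 = congruence_from_pairs(np.exp(3 * snv), beta ** 3 + 5).rho
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(UndefinedMetricError):
            congruence_from_pairs(np.ones(4), np.ones(4))

    def test_beta_distance_symmetry(self, rng):
        beta = _beta(rng.random((200, 5)))
        dm = beta_distance(beta, [f"S{j}" for j in range(5)])
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
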