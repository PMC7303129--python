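"""Clone-tree search against an enumeration oracle, labelling, trunk
fraction and event timing."""

import itertools

import numpy as np
import pytest

from clonalith.errors import TreeRootError, UndefinedMetricError
from clonalith.inference import ClusterSet
from clonalith.phylo import (
    build_tree, label_tree, metastasis_seeding, order_mutation_vs_scna,
    time_gain, to_newick, tree_violation, trunk_fraction,
)


def oracle_trees(k, root):
    """Independent enumeration of rooted labeled trees via parent vectors
    with an explicit cycle check."""
    others = [i for i in range(k) if i != root]
    for combo in itertools.product(*[[p for p in range(k) if p != i]
                                     for i in others]):
        parent = np.full(k, -1, dtype=int)
        for node, p in zip(others, combo):
            parent[node] = p
        seen_all = True
        for node in others:
            hops, cur = 0, node
            while parent[cur] >= 0 and hops <= k:
                cur = parent[cur]
                hops += 1
            if cur != root:
                seen_all = False
                break
        if seen_all:
            yield parent


def oracle_score(parent, ccf, eps):
    """Brute-force re-implementation of the three constraint rules."""
    k, s = ccf.shape
    total = 0.0
    anc = {i: set() for i in range(k)}
    for i in range(k):
        cur = parent[i]
        while cur >= 0:
            anc[i].add(cur)
            cur = parent[cur]
    for child in range(k):
        p = parent[child]
        if p >= 0:
            for j in range(s):
                total += max(0.0, ccf[child, j] - ccf[p, j] - eps)
    for p in range(k):
        kids = [c for c in range(k) if parent[c] == p]
        if kids:
            for j in range(s):
                total += max(0.0, sum(ccf[c, j] for c in kids) - ccf[p, j] - eps)
    for d in range(k):
        for a in anc[d]:
            up = max(max(0.0, ccf[d, j] - ccf[a, j] - eps) for j in range(s))
            down = max(max(0.0, ccf[a, j] - ccf[d, j] - eps) for j in range(s))
            total += min(up, down)
    return total


class TestBuildTree:
    def test_single_cluster(self):
        t = build_tree(np.array([[1.0, 1.0]]))
        assert t.parent.tolist() == [-1] and t.violation == 0.0

    def test_crossing_forces_siblings(self):
        """A=(1,1), B=(0.6,0.1), C=(0.3,0.8): B and C cross, so they must be
        siblings under A."""
        ccf = np.array([[1.0, 1.0], [0.6, 0.1], [0.3, 0.8]])
        t = build_tree(ccf)
        assert t.parent.tolist() == [-1, 0, 0]
        assert t.violation == 0.0

    def test_pigeonhole_forces_chain(self):
        """A=(1,1), B=(0.7,0.6), C=(0.4,0.3): siblings break pigeonhole
        (0.7+0.4 > 1), the chain A->B->C is feasible."""
        ccf = np.array([[1.0, 1.0], [0.7, 0.6], [0.4, 0.3]])
        t = build_tree(ccf)
        assert t.parent.tolist() == [-1, 0, 1]

    def test_matches_enumeration_oracle(self, rng):
        """Returned tree minimizes the oracle score over all rooted trees."""
        for trial in range(30):
            k = int(rng.integers(2, 6))
            ccf = np.vstack([np.ones(2), rng.uniform(0, 0.95, (k - 1, 2))])
            t = build_tree(ccf, tolerance=0.05)
            scores = [oracle_score(p, ccf, 0.05) for p in oracle_trees(k, 0)]
            assert t.violation == pytest.approx(min(scores), abs=1e-6)
            assert tree_violation(t.parent, ccf, 0.05) == pytest.approx(
                t.violation, abs=1e-9)

    def test_no_truncal_cluster(self):
        with pytest.raises(TreeRootError):
            build_tree(np.array([[0.5, 0.4], [0.3, 0.2]]))

    def test_greedy_used_above_exhaustive_cap(self, rng):
        k = 10
        ccf = np.vstack([np.ones(2), rng.uniform(0, 0.9, (k - 1, 2))])
        t = build_tree(ccf, exhaustive_max=8)
        # valid rooted tree: every node reaches the root
        for node in range(k):
            cur, hops = node, 0
            while t.parent[cur] >= 0:
                cur = t.parent[cur]
                hops += 1
                assert hops <= k
            assert cur == t.root


class TestLabels:
    def test_partition_exhaustive_exclusive(self, rng):
        ccf = np.array([[1.0, 1.0, 1.0], [0.5, 0.4, 0.2], [0.0, 0.3, 0.0],
                        [0.05, 0.02, 0.04]])
        t = label_tree(build_tree(ccf))
        assert t.labels[0] == "trunk"
        assert t.labels[1] == "internal_branch"
        assert t.labels[2] == "leaf"
        assert len(t.labels) == 4
        assert all(l in ("trunk", "internal_branch", "leaf") for l in t.labels)

    def test_leaf_region_annotation(self):
        ccf = np.array([[1.0, 1.0], [0.0, 0.6]])
        t = label_tree(build_tree(ccf, samples=["T01", "T06"]),
                       )
        assert t.labels[1] == "leaf"
        assert t.leaf_regions[1] == ["T06"]

    def test_branch_in_two_of_four(self):
        ccf = np.array([[1.0] * 4, [0.4, 0.4, 0.0, 0.0]])
        t = label_tree(build_tree(ccf))
        assert t.labels[1] == "internal_branch"

    def test_oval_matrix_ordering(self):
        ccf = np.array([[1.0, 1.0], [0.0, 0.4], [0.5, 0.5]])
        t = label_tree(build_tree(ccf, samples=["T01", "T02"]))
        assert list(t.oval_matrix.index)[0] == "cluster0"  # trunk first


class TestTrunkFraction:
    def _cluster_set(self, centroids, sizes):
        assign = np.repeat(np.arange(len(sizes)), sizes)
        return ClusterSet(centroids=np.asarray(centroids, float),
                          assignment=assign,
                          samples=["A", "B"])

    def test_all_truncal(self):
        cs = self._cluster_set([[1.0, 1.0]], [50])
        t = label_tree(build_tree(cs))
        assert trunk_fraction(cs, t) == 1.0

    def test_seventy_percent(self):
        cs = self._cluster_set([[1.0, 1.0], [0.4, 0.2]], [70, 30])
        t = label_tree(build_tree(cs))
        assert trunk_fraction(cs, t) == pytest.approx(0.70)

    def test_no_assigned_mutations(self):
        cs = self._cluster_set([[1.0, 1.0]], [10])
        cs.assignment = np.full(10, -1)
        t = label_tree(build_tree(cs))
        with pytest.raises(UndefinedMetricError):
            trunk_fraction(cs, t)


class TestTiming:
    def test_no_duplicated_mutations_means_t_zero(self):
        assert time_gain(n1=50, n2=0, gain_type="2+1").t == 0.0

    def test_closed_form_2plus1(self):
        res = time_gain(n1=220, n2=20, gain_type="2+1")
        assert res.t == pytest.approx(60 / 260, abs=1e-12)

    def test_closed_form_2plus0(self):
        res = time_gain(n1=100, n2=50, gain_type="2+0")
        assert res.t == pytest.approx(0.5)

    def test_min_support(self):
        res = time_gain(n1=4, n2=2, gain_type="2+1")
        assert res.t is None and "support" in res.reason

    @pytest.mark.parametrize("gain_type", ["2+1", "2+0"])
    def test_closed_form_matches_accrual_simulation(self, gain_type, rng):
        """Event-level constant-rate accrual: mutations arrive uniformly in
        time on each allele copy; copies double at the gain time."""
        for t_true in (0.2, 0.5, 0.8):
            n1 = n2 = 0
            pre_copies = 2
            post_copies = 3 if gain_type == "2+1" else 2
            dup_copies = 1  # copies whose pre-gain mutations get duplicated
            rate = 400
            n_pre = rng.poisson(rate * t_true * pre_copies)
            n_post = rng.poisson(rate * (1 - t_true) * post_copies)
            for _ in range(n_pre):
                copy = rng.integers(pre_copies)
                if copy < dup_copies:
                    n2 += 1
                elif gain_type == "2+0":
                    pass        # mutation on the lost allele disappears
                else:
                    n1 += 1
            n1 += n_post
            est = time_gain(n1=n1, n2=n2, gain_type=gain_type).t
            assert est == pytest.approx(t_true, abs=0.08)


class TestOrdering:
    def test_cnloh_multiplicity_two_is_before(self):
        res = order_mutation_vs_scna(2, 2, 0, clonal=True)
        assert res.order_relation == "before"

    def test_cnloh_multiplicity_one_is_after(self):
        assert order_mutation_vs_scna(1, 2, 0, clonal=True).order_relation == "after"

    def test_gain_multiplicity_one_needs_early_gain(self):
        amb = order_mutation_vs_scna(1, 3, 1, clonal=True)
        assert amb.order_relation == "undetermined"
        late = order_mutation_vs_scna(1, 3, 1, clonal=True, gain_time=0.3)
        assert late.order_relation == "after"

    def test_diploid_uninformative(self):
        assert order_mutation_vs_scna(1, 2, 1, clonal=True).order_relation == \
            "undetermined"

    def test_subclonal_undetermined(self):
        res = order_mutation_vs_scna(2, 2, 0, clonal=False)
        assert res.order_relation == "undetermined"


class TestAnnotation:
    def test_newick_contains_all_clusters(self):
        ccf = np.array([[1.0, 1.0], [0.5, 0.4], [0.2, 0.1]])
        t = build_tree(ccf)
        nwk = to_newick(t, [100, 40, 10])
        assert nwk.endswith(";")
        for k in range(3):
            assert f"cluster{k}" in nwk

    def test_metastasis_seeding(self):
        # met shares the non-truncal cluster 1 with T02 only
        ccf = np.array([[1.0, 1.0, 1.0], [0.0, 0.5, 0.45], [0.4, 0.0, 0.0]])
        cs = ClusterSet(centroids=ccf, assignment=np.repeat([0, 1, 2], 10),
                        samples=["T01", "T02", "M01"])
        t = label_tree(build_tree(cs))
        assert metastasis_seeding(cs, t, ["T01", "T02"], "M01") == ["T02"]
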