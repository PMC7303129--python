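"""Clone trees from cluster CCFs, trunk/branch/leaf labels, and event timing.

Tree inference searches rooted trees over the clone clusters for the one
that best satisfies three constraints, per sample:

* lineage rule — a child's CCF cannot exceed its parent's;
* pigeonhole principle — sibling CCFs cannot sum beyond their parent's;
* crossing rule — two clusters whose CCF ordering flips between samples
  cannot be in an ancestor-descendant relationship.

For small cluster counts the search is exhaustive (all labeled trees rooted
at the truncal cluster); the returned tree minimizes the total constraint
violation, tie-broken by shallower depth then lexicographic parent vector.

Copy-number gains are timed from the ratio of duplicated to non-duplicated
clonal mutations: under constant-rate accrual a gain at relative molecular
time t leaves t = 3*N2/(N1 + 2*N2) for a 2+1 gain and t = 2*N2/(N1 + 2*N2)
for copy-neutral LOH (2+0), where N2 / N1 count multiplicity-2 /
multiplicity-1 clonal mutations in the gained segment. Early gains have few
duplicated mutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import TreeRootError, UndefinedMetricError
from .inference import ClusterSet

TRUNK_TOLERANCE = 0.1       # "CCF = 1 in all samples" within this
PRESENCE_THRESHOLD = 0.1    # "present in a sample" means CCF above this


# ---------------------------------------------------------------------------
# violation function (single source of truth for all tree scoring)
# ---------------------------------------------------------------------------

def _pairwise_penalties(ccf: np.ndarray, eps: float):
    """L[a, b]: lineage penalty if a is parent of b; cross[a, b]: crossing
    penalty if a and b are in an ancestor-descendant relation."""
    diff = ccf[None, :, :] - ccf[:, None, :]          # (a,b,s) = ccf[b]-ccf[a]
    excess = np.maximum(0.0, diff - eps)
    lineage = excess.sum(axis=2)
    up = excess.max(axis=2)                           # b exceeds a somewhere
    cross = np.minimum(up, up.T)
    return lineage, cross


def tree_violation(parent: np.ndarray, ccf: np.ndarray, eps: float = 0.05) -> float:
    """Total lineage + pigeonhole + crossing violation of a rooted tree."""
    parent = np.asarray(parent)
    k = len(parent)
    lineage, cross = _pairwise_penalties(ccf, eps)
    total = 0.0
    for child in range(k):
        p = parent[child]
        if p >= 0:
            total += lineage[p, child]
    # pigeonhole per internal node
    child_sum = np.zeros_like(ccf)
    for child in range(k):
        p = parent[child]
        if p >= 0:
            child_sum[p] += ccf[child]
    for p in range(k):
        total += np.maximum(0.0, child_sum[p] - ccf[p] - eps).sum()
    # crossing over every ancestor-descendant pair
    for node in range(k):
        a = parent[node]
        while a >= 0:
            total += cross[a, node]
            a = parent[a]
    return float(total)


def _tree_depth(parent: np.ndarray) -> int:
    depth = 0
    for node in range(len(parent)):
        d, a = 0, parent[node]
        while a >= 0:
            d += 1
            a = parent[a]
        depth = max(depth, d)
    return depth


# ---------------------------------------------------------------------------
# tree search
# ---------------------------------------------------------------------------

def _prufer_to_parent(seq: tuple, k: int, root: int) -> np.ndarray | None:
    """Decode a Pruefer sequence into a parent vector rooted at ``root``."""
    degree = np.ones(k, dtype=int)
    for x in seq:
        degree[x] += 1
    adj = [[] for _ in range(k)]
    ptr = 0
    leaves = sorted(i for i in range(k) if degree[i] == 1)
    import heapq
    heap = leaves[:]
    heapq.heapify(heap)
    for x in seq:
        leaf = heapq.heappop(heap)
        adj[leaf].append(x)
        adj[x].append(leaf)
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(heap, x)
    u = heapq.heappop(heap)
    v = heapq.heappop(heap)
    adj[u].append(v)
    adj[v].append(u)
    parent = np.full(k, -1, dtype=int)
    seen = np.zeros(k, dtype=bool)
    stack = [root]
    seen[root] = True
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if not seen[nb]:
                seen[nb] = True
                parent[nb] = node
                stack.append(nb)
    return parent


def _all_rooted_trees(k: int, root: int):
    """Every labeled rooted tree on k nodes with the given root."""
    if k == 1:
        yield np.array([-1])
        return
    if k == 2:
        parent = np.full(2, -1, dtype=int)
        parent[1 - root] = root
        yield parent
        return
    for seq in itertools.product(range(k), repeat=k - 2):
        yield _prufer_to_parent(seq, k, root)


@dataclass
class CloneTree:
    """Rooted tree over clone clusters with annotation fields."""

    parent: np.ndarray
    root: int
    ccf: np.ndarray                  # K x S centroid matrix used for inference
    samples: list[str]
    violation: float = 0.0
    labels: list[str] | None = None            # trunk | internal_branch | leaf
    leaf_regions: dict = field(default_factory=dict)  # node -> [sample ids]
    oval_matrix: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return len(self.parent)

    def children(self, node: int) -> np.ndarray:
        return np.flatnonzero(self.parent == node)

    def depth(self) -> int:
        return _tree_depth(self.parent)


def _find_root(ccf: np.ndarray, trunk_tolerance: float) -> int:
    mins = ccf.min(axis=1)
    root = int(np.argmax(mins))
    if mins[root] < 1.0 - trunk_tolerance:
        raise TreeRootError(
            f"no truncal cluster: best min-CCF {mins[root]:.3f} < "
            f"{1 - trunk_tolerance:.2f} in some sample")
    return root


def build_tree(clusters: ClusterSet | np.ndarray, tolerance: float = 0.05,
               trunk_tolerance: float = TRUNK_TOLERANCE,
               exhaustive_max: int = 8,
               samples: Sequence[str] | None = None) -> CloneTree:
    """Infer the clone tree minimizing the constraint-violation score.

    Exhaustive over all rooted labeled trees for up to ``exhaustive_max``
    clusters; above that, greedy constraint-guided insertion in order of
    descending mean CCF (approximate). Ties break to (lower violation,
    shallower tree, lexicographically smaller parent vector).
    """
    if isinstance(clusters, ClusterSet):
        ccf = clusters.centroids
        samples = clusters.samples
    else:
        ccf = np.asarray(clusters, dtype=float)
        if ccf.ndim == 1:
            ccf = ccf[:, None]
        if samples is None:
            samples = [f"S{j}" for j in range(ccf.shape[1])]
    k = len(ccf)
    root = _find_root(ccf, trunk_tolerance)
    if k == 1:
        return CloneTree(parent=np.array([-1]), root=0, ccf=ccf,
                         samples=list(samples), violation=0.0)

    if k <= exhaustive_max:
        best = None
        for parent in _all_rooted_trees(k, root):
            score = round(tree_violation(parent, ccf, tolerance), 9)
            key = (score, _tree_depth(parent), tuple(parent))
            if best is None or key < best[0]:
                best = (key, parent)
        parent = best[1]
        violation = best[0][0]
    else:
        order = sorted((i for i in range(k) if i != root),
                       key=lambda i: (-ccf[i].mean(), i))
        parent = np.full(k, -1, dtype=int)
        placed = [root]
        for node in order:
            best_key = None
            for cand in placed:
                parent[node] = cand
                sub = placed + [node]
                score = round(_partial_violation(parent, ccf, tolerance, sub), 9)
                key = (score, cand)
                if best_key is None or key < best_key[0]:
                    best_key = (key, cand)
            parent[node] = best_key[1]
            placed.append(node)
        violation = round(tree_violation(parent, ccf, tolerance), 9)

    return CloneTree(parent=parent, root=root, ccf=ccf, samples=list(samples),
                     violation=float(violation))


def _partial_violation(parent, ccf, eps, nodes) -> float:
    mask = np.zeros(len(parent), dtype=bool)
    mask[nodes] = True
    sub_parent = np.full(len(parent), -1, dtype=int)
    for i in nodes:
        if parent[i] >= 0 and mask[parent[i]]:
            sub_parent[i] = parent[i]
    return tree_violation(sub_parent, ccf, eps)


# ---------------------------------------------------------------------------
# labelling
# ---------------------------------------------------------------------------

def label_tree(tree: CloneTree, clusters: ClusterSet | None = None,
               presence_threshold: float = PRESENCE_THRESHOLD,
               trunk_tolerance: float = TRUNK_TOLERANCE,
               spatial_order: Sequence[str] | None = None) -> CloneTree:
    """Partition clusters into trunk / internal_branch / leaf.

    Trunk: CCF ~ 1 (>= 1 - tolerance) in every sample. Leaf: present (CCF
    above the presence threshold) in exactly one sample. Everything else is
    an internal branch. Also attaches the oval-plot matrix (cluster x sample
    CCF, samples in spatial order, clusters ordered trunk, branch, leaf).
    """
    ccf = tree.ccf
    labels = []
    leaf_regions: dict[int, list[str]] = {}
    for k in range(tree.n_clusters):
        present = [tree.samples[j] for j in np.flatnonzero(ccf[k] > presence_threshold)]
        if np.all(ccf[k] >= 1.0 - trunk_tolerance):
            labels.append("trunk")
        elif len(present) == 1:
            labels.append("leaf")
            leaf_regions[k] = present
        else:
            labels.append("internal_branch")
    tree.labels = labels
    tree.leaf_regions = leaf_regions
    cols = list(spatial_order) if spatial_order is not None else list(tree.samples)
    rank = {"trunk": 0, "internal_branch": 1, "leaf": 2}
    row_order = sorted(range(tree.n_clusters), key=lambda k: (rank[labels[k]], k))
    mat = pd.DataFrame(ccf, columns=tree.samples).reindex(columns=cols)
    tree.oval_matrix = mat.iloc[row_order]
    tree.oval_matrix.index = [f"cluster{k}" for k in row_order]
    return tree


def trunk_fraction(clusters: ClusterSet, tree: CloneTree) -> float:
    """Fraction of assigned mutations lying in trunk clusters."""
    if tree.labels is None:
        tree = label_tree(tree)
    assigned = clusters.assignment >= 0
    total = int(assigned.sum())
    if total == 0:
        raise UndefinedMetricError("no assigned mutations")
    trunk_ids = [k for k, lab in enumerate(tree.labels) if lab == "trunk"]
    in_trunk = np.isin(clusters.assignment, trunk_ids) & assigned
    return float(in_trunk.sum() / total)


# ---------------------------------------------------------------------------
# timing
# ---------------------------------------------------------------------------

@dataclass
class TimingResult:
    event: str
    n1: int = 0
    n2: int = 0
    t: float | None = None
    order_relation: str | None = None   # before | after | undetermined
    reason: str | None = None


def time_gain(multiplicities: Sequence[int] | None = None, *,
              n1: int | None = None, n2: int | None = None,
              gain_type: str = "2+1", min_support: int = 10,
              event: str = "gain") -> TimingResult:
    """Relative molecular time of a copy-number duplication from clonal
    mutation multiplicities inside the gained segment.

    ``gain_type`` is "2+1" (single-copy gain) or "2+0" (copy-neutral LOH).
    """
    if multiplicities is not None:
        m = np.asarray(multiplicities)
        n1 = int((m == 1).sum())
        n2 = int((m == 2).sum())
    if n1 is None or n2 is None:
        raise ValueError("provide multiplicities or n1/n2")
    if n1 + n2 < min_support:
        return TimingResult(event=event, n1=n1, n2=n2, t=None,
                            reason=f"support {n1 + n2} < {min_support}")
    if gain_type == "2+1":
        t = 3.0 * n2 / (n1 + 2.0 * n2)
    elif gain_type == "2+0":
        t = 2.0 * n2 / (n1 + 2.0 * n2)
    else:
        raise ValueError(f"unknown gain type {gain_type!r}")
    return TimingResult(event=event, n1=n1, n2=n2, t=float(np.clip(t, 0.0, 1.0)))


def order_mutation_vs_scna(multiplicity: int, total_cn: int, minor_cn: int, *,
                           clonal: bool, gain_time: float | None = None,
                           late_threshold: float = 0.5,
                           event: str = "mutation-vs-SCNA") -> TimingResult:
    """Order a driver mutation relative to the gain/LOH of its segment.

    In a 2+0 (copy-neutral LOH) region a clonal mutation at multiplicity 2
    predates the LOH (it was duplicated by it); multiplicity 1 postdates it.
    In a gained (2+1) region multiplicity 2 means before the gain;
    multiplicity 1 is 'after' only when the gain itself is timed early
    (t < ``late_threshold``), otherwise the un-gained-allele scenario cannot
    be excluded and the call is undetermined.
    """
    res = TimingResult(event=event)
    if not clonal:
        res.order_relation = "undetermined"
        res.reason = "mutation subclonal"
        return res
    major = total_cn - minor_cn
    if total_cn == 2 and minor_cn == 1:
        res.order_relation = "undetermined"
        res.reason = "diploid segment carries no timing information"
        return res
    if total_cn == 2 and minor_cn == 0:         # CNLOH
        res.order_relation = "before" if multiplicity == 2 else "after"
        return res
    if major >= 2:                               # gained segment
        if multiplicity >= 2:
            res.order_relation = "before"
        elif gain_time is not None and gain_time < late_threshold:
            res.order_relation = "after"
        else:
            res.order_relation = "undetermined"
            res.reason = "multiplicity 1 in a gain: allele assignment ambiguous"
        return res
    res.order_relation = "undetermined"
    res.reason = f"uninformative segment state {total_cn}/{minor_cn}"
    return res


# ---------------------------------------------------------------------------
# annotation helpers
# ---------------------------------------------------------------------------

def metastasis_seeding(clusters: ClusterSet, tree: CloneTree,
                       primary_samples: Sequence[str],
                       metastasis_sample: str,
                       presence_threshold: float = PRESENCE_THRESHOLD) -> list[str]:
    """Primary region(s) sharing the most non-truncal clusters with the
    metastasis — the likely seeding region(s)."""
    if tree.labels is None:
        tree = label_tree(tree)
    ccf = pd.DataFrame(tree.ccf, columns=tree.samples)
    met = ccf[metastasis_sample] > presence_threshold
    shared_counts = {}
    for s in primary_samples:
        shared = 0
        for k in range(tree.n_clusters):
            if tree.labels[k] != "trunk" and met[k] and ccf.loc[k, s] > presence_threshold:
                shared += 1
        shared_counts[s] = shared
    best = max(shared_counts.values())
    return [s for s, c in shared_counts.items() if c == best and best > 0]


def to_newick(tree: CloneTree, mutation_counts: Sequence[int] | None = None) -> str:
    """Newick with cluster IDs as labels and mutation counts as branch
    lengths (branch lengths proportional to the number of substitutions)."""
    counts = (np.asarray(mutation_counts) if mutation_counts is not None
              else np.zeros(tree.n_clusters, dtype=int))

    def render(node: int) -> str:
        kids = tree.children(node)
        label = f"cluster{node}:{counts[node]}"
        if len(kids) == 0:
            return label
        return "(" + ",".join(render(int(c)) for c in kids) + ")" + label

    return render(tree.root) + ";"


def tree_to_json(tree: CloneTree) -> dict:
    return {
        "parent": tree.parent.tolist(),
        "root": int(tree.root),
        "labels": tree.labels,
        "samples": tree.samples,
        "ccf": tree.ccf.tolist(),
        "violation": tree.violation,
        "leaf_regions": {str(k): v for k, v in tree.leaf_regions.items()},
    }
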