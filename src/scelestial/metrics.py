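"""Tree-comparison measures: normalized pairwise-path distance and split
similarity.

Both measures compare an inferred lineage tree with a ground-truth tree
over the same set of samples.  The distance measure normalizes each tree's
sample-to-sample path-length matrix to sum to one over unordered pairs and
takes the L1 difference — scale-free, in [0, 2].  The split similarity
scores every pair of edge-induced sample bipartitions by their agreement,
finds a maximum-weight one-to-one matching between the two split sets, and
normalizes by the reference tree's self-matching score — in [0, 1] when the
reference has at most as many edges.

Clone-based ground truths (each clone an internal node, its member samples
attached by zero-length edges) are converted with
:func:`clone_tree_to_sample_tree` so both tree flavors are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .tree import INFERRED, SAMPLE, LineageTree

__all__ = [
    "PairwiseDistanceMatrix",
    "Split",
    "pairwise_distance_matrix",
    "tree_distance",
    "split_pair_similarity",
    "split_similarity_score",
    "clone_tree_to_sample_tree",
    "tree_splits",
]


@dataclass
class PairwiseDistanceMatrix:
    sample_ids: List[str]
    raw: np.ndarray
    normalized: np.ndarray


def _node_index(tree: LineageTree) -> Dict[str, int]:
    return {n: i for i, n in enumerate(tree.nodes)}


def pairwise_distance_matrix(tree: LineageTree, weight: str = "edge_cost") -> PairwiseDistanceMatrix:
    """Path lengths between all sample pairs along tree edges.

    ``weight``: ``edge_cost`` uses the stored branch costs, ``unit`` counts
    edges.  The normalized form divides by the total over unordered pairs
    (all-zero when the total is zero — e.g. a single-clone star).
    """
    if weight not in ("edge_cost", "unit"):
        raise ValueError(f"unknown weight {weight!r}")
    idx = _node_index(tree)
    n_all = len(idx)
    samples = sorted(tree.sample_ids)
    if not samples:
        raise ValueError("tree has no samples")
    rows, cols, data = [], [], []
    for u, v, c in tree.edges:
        w = c if weight == "edge_cost" else 1.0
        rows.append(idx[u])
        cols.append(idx[v])
        data.append(w)
    g = csr_matrix((data, (rows, cols)), shape=(n_all, n_all))
    sidx = np.array([idx[s] for s in samples])
    d = shortest_path(g, directed=False, indices=sidx)[:, sidx]
    d = np.asarray(d)
    np.fill_diagonal(d, 0.0)
    total = d.sum() / 2.0  # unordered pairs
    norm = np.zeros_like(d) if total == 0 else d / total
    return PairwiseDistanceMatrix(samples, d, norm)


def tree_distance(T: LineageTree, T2: LineageTree, weight: str = "edge_cost") -> float:
    """L1 distance between the normalized pairwise matrices; in [0, 2]."""
    p1 = pairwise_distance_matrix(T, weight)
    p2 = pairwise_distance_matrix(T2, weight)
    if p1.sample_ids != p2.sample_ids:
        raise ValueError("trees cover different sample sets")
    diff = np.abs(p1.normalized - p2.normalized)
    return float(diff.sum() / 2.0)  # unordered pairs


@dataclass(frozen=True)
class Split:
    """Unordered bipartition {A, B} of the sample set induced by an edge."""

    side_a: frozenset
    side_b: frozenset

    def __post_init__(self):
        if self.side_a & self.side_b:
            raise ValueError("split sides overlap")
        if not self.side_a or not self.side_b:
            raise ValueError("split sides must be nonempty")

    @property
    def ground_set(self) -> frozenset:
        return self.side_a | self.side_b

    def __eq__(self, other):
        return isinstance(other, Split) and {self.side_a, self.side_b} == {
            other.side_a,
            other.side_b,
        }

    def __hash__(self):
        return hash(frozenset((self.side_a, self.side_b)))


def split_pair_similarity(s1: Split, s2: Split) -> int:
    """Number of samples split consistently by the two bipartitions:
    max(|A1&A2| + |B1&B2|, |A1&B2| + |B1&A2|)."""
    if s1.ground_set != s2.ground_set:
        raise ValueError("splits over different sample sets")
    straight = len(s1.side_a & s2.side_a) + len(s1.side_b & s2.side_b)
    crossed = len(s1.side_a & s2.side_b) + len(s1.side_b & s2.side_a)
    return max(straight, crossed)


def tree_splits(tree: LineageTree) -> List[Split]:
    """Sample bipartitions induced by every edge (edges whose removal
    leaves all samples on one side induce no split and are dropped)."""
    samples = set(tree.sample_ids)
    adj = tree.adjacency()
    out = []
    for u, v, _ in tree.edges:
        # samples on v's side: reachable from v without crossing edge (u, v)
        seen = {v}
        stack = [v]
        side = set()
        while stack:
            x = stack.pop()
            if x in samples:
                side.add(x)
            for y in adj[x]:
                if y == u and x == v:
                    continue
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        other = samples - side
        if side and other:
            out.append(Split(frozenset(side), frozenset(other)))
    return out


def split_similarity_score(
    T_ref: LineageTree, T: LineageTree, return_both: bool = False
):
    """Maximum-weight matching score between the two trees' split sets,
    normalized by the reference tree's self-score (samples x edges).

    The first argument is the reference (ground-truth) tree.  With
    ``return_both`` the score normalized by the second tree's self-score is
    returned as well.
    """
    if set(T_ref.sample_ids) != set(T.sample_ids):
        raise ValueError("trees cover different sample sets")
    s_ref = tree_splits(T_ref)
    s_inf = tree_splits(T)
    if not s_ref or not s_inf:
        raise ValueError("a tree with no informative edges has no splits")
    score = np.zeros((len(s_ref), len(s_inf)))
    for i, a in enumerate(s_ref):
        for j, b in enumerate(s_inf):
            score[i, j] = split_pair_similarity(a, b)
    ri, ci = linear_sum_assignment(score, maximize=True)
    matched = float(score[ri, ci].sum())
    n = len(T_ref.sample_ids)
    self_ref = n * len(s_ref)
    if not return_both:
        return matched / self_ref
    return matched / self_ref, matched / (n * len(s_inf))


def clone_tree_to_sample_tree(
    clone_edges: Sequence[Tuple[str, str, float]],
    memberships: Dict[str, str],
    clone_ids: Sequence[str] = None,
) -> LineageTree:
    """Expand a clone tree into a sample tree: every clone becomes an
    inferred node, every member sample hangs off its clone with a
    zero-length edge; clone-clone edges keep their weights.

    ``memberships`` maps sample id -> clone id; every sample must be
    assigned.  ``clone_ids`` lists clones explicitly (needed for a
    single-clone tree with no edges).
    """
    tree = LineageTree()
    clones = set(clone_ids or [])
    for a, b, _ in clone_edges:
        clones.update((a, b))
    if not clones:
        raise ValueError("clone tree is empty")
    for c in sorted(clones):
        tree.add_node(f"clone:{c}", INFERRED)
    for a, b, w in clone_edges:
        tree.add_edge(f"clone:{a}", f"clone:{b}", w)
    for sample, clone in memberships.items():
        if f"clone:{clone}" not in tree.nodes:
            raise ValueError(f"sample {sample!r} assigned to unknown clone {clone!r}")
        tree.add_node(sample, SAMPLE)
        tree.add_edge(sample, f"clone:{clone}", 0.0)
    tree.validate()
    return tree
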