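"""Lineage-tree container and post-processing.

A :class:`LineageTree` holds the observed samples plus any inferred
ancestral genotypes as nodes of an unrooted tree whose edge costs are
sequence costs.  Post-processing covers missing-value imputation (each
missing locus of a sample takes the most abundant state among its tree
neighbors), suppression of redundant inferred nodes, rooting at the sample
closest to a reference genotype, and Newick serialization.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cost import CostModel, DEFAULT_COST_MODEL
from .genotype import MISSING, CellSequence, state_to_token

__all__ = [
    "LineageTree",
    "RootedLineageTree",
    "impute_missing",
    "collapse_redundant",
    "root_by_reference",
    "to_newick",
    "from_newick",
]

SAMPLE = "sample"
INFERRED = "inferred"


@dataclass
class LineageTree:
    """Unrooted tree over samples and inferred ancestors.

    ``nodes`` maps node id -> (kind, sequence); sequences may be None for
    trees read back from Newick (metrics only need the structure).
    ``edges`` is a list of (u, v, cost).
    """

    nodes: Dict[str, Tuple[str, Optional[CellSequence]]] = field(default_factory=dict)
    edges: List[Tuple[str, str, float]] = field(default_factory=list)

    def add_node(self, node_id: str, kind: str, sequence: Optional[CellSequence] = None):
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id!r}")
        if kind not in (SAMPLE, INFERRED):
            raise ValueError(f"bad node kind {kind!r}")
        self.nodes[node_id] = (kind, sequence)

    def add_edge(self, u: str, v: str, cost: float):
        if u not in self.nodes or v not in self.nodes:
            raise ValueError(f"edge endpoints {u!r}-{v!r} not both in tree")
        self.edges.append((u, v, float(cost)))

    # -- queries ---------------------------------------------------------
    @property
    def sample_ids(self) -> List[str]:
        return [n for n, (k, _) in self.nodes.items() if k == SAMPLE]

    @property
    def inferred_ids(self) -> List[str]:
        return [n for n, (k, _) in self.nodes.items() if k == INFERRED]

    def kind(self, node_id: str) -> str:
        return self.nodes[node_id][0]

    def sequence(self, node_id: str) -> Optional[CellSequence]:
        return self.nodes[node_id][1]

    def set_sequence(self, node_id: str, seq: CellSequence):
        self.nodes[node_id] = (self.nodes[node_id][0], seq)

    def adjacency(self) -> Dict[str, Dict[str, float]]:
        adj: Dict[str, Dict[str, float]] = {n: {} for n in self.nodes}
        for u, v, c in self.edges:
            adj[u][v] = c
            adj[v][u] = c
        return adj

    def degree(self, node_id: str) -> int:
        d = 0
        for u, v, _ in self.edges:
            if u == node_id or v == node_id:
                d += 1
        return d

    def total_cost(self) -> float:
        return float(sum(c for _, _, c in self.edges))

    def validate(self):
        """Assert connectivity and acyclicity (n nodes, n-1 edges, one component)."""
        n = len(self.nodes)
        if len(self.edges) != n - 1:
            raise ValueError(f"{n} nodes but {len(self.edges)} edges — not a tree")
        if n == 0:
            return
        adj = self.adjacency()
        seen = set()
        stack = [next(iter(self.nodes))]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj[x])
        if len(seen) != n:
            raise ValueError("tree is disconnected")

    def copy(self) -> "LineageTree":
        return LineageTree(dict(self.nodes), list(self.edges))


@dataclass
class RootedLineageTree:
    """A lineage tree with a designated root node."""

    tree: LineageTree
    root: str

    def __post_init__(self):
        if self.root not in self.tree.nodes:
            raise ValueError(f"root {self.root!r} not a node of the tree")

    def parents(self) -> Dict[str, Optional[str]]:
        """Parent map induced by orienting all edges away from the root."""
        adj = self.tree.adjacency()
        parent: Dict[str, Optional[str]] = {self.root: None}
        stack = [self.root]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in parent:
                    parent[y] = x
                    stack.append(y)
        return parent


# -- post-processing -----------------------------------------------------

def impute_missing(tree: LineageTree, model: CostModel = DEFAULT_COST_MODEL) -> LineageTree:
    """Replace every missing locus of a sample by the most abundant state
    among its tree neighbors at that locus; recompute edge costs.

    One synchronous pass over pre-imputation neighbor states.  Inferred
    nodes are already missing-free (the DP never assigns the missing state),
    so only neighbors that are themselves unimputed samples can contribute a
    missing state — those are ignored in the tally.  Ties break to the
    lowest canonical state code.  In the degenerate case where no neighbor
    offers an observed state at that locus, the most abundant observed state
    at the locus across the whole tree is used (and state code 0 if the
    locus is missing everywhere).
    """
    out = tree.copy()
    adj = tree.adjacency()
    new_seqs: Dict[str, CellSequence] = {}
    for node_id, (kind, seq) in tree.nodes.items():
        if seq is None or not np.any(seq.states == MISSING):
            continue
        states = seq.states.copy()
        for t in np.nonzero(states == MISSING)[0]:
            votes = Counter()
            for nbr in adj[node_id]:
                nseq = tree.sequence(nbr)
                if nseq is None:
                    continue
                s = int(nseq.states[t])
                if s != MISSING:
                    votes[s] += 1
            if not votes:
                for other, (_, oseq) in tree.nodes.items():
                    if other == node_id or oseq is None:
                        continue
                    s = int(oseq.states[t])
                    if s != MISSING:
                        votes[s] += 1
            if votes:
                best = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))[0]
            else:
                best = 0
            states[t] = best
        new_seqs[node_id] = CellSequence(seq.sample_id, states)
    for node_id, seq in new_seqs.items():
        out.set_sequence(node_id, seq)
    out.edges = [
        (u, v, model.sequence_cost(out.sequence(u), out.sequence(v)))
        if out.sequence(u) is not None and out.sequence(v) is not None
        else (u, v, c)
        for u, v, c in out.edges
    ]
    return out


def collapse_redundant(tree: LineageTree) -> LineageTree:
    """Suppress inferred nodes of degree <= 2.

    Degree-2 inferred nodes are contracted (their two incident edges merge
    with summed cost); degree-1 inferred nodes are pruned.  Repeats to a
    fixpoint, so chains collapse fully; idempotent.
    """
    nodes = dict(tree.nodes)
    adj: Dict[str, Dict[str, float]] = {n: {} for n in nodes}
    for u, v, c in tree.edges:
        adj[u][v] = c
        adj[v][u] = c
    changed = True
    while changed:
        changed = False
        for node_id in list(nodes):
            kind = nodes[node_id][0]
            if kind != INFERRED:
                continue
            deg = len(adj[node_id])
            if deg == 1:
                (nbr,) = adj[node_id]
                del adj[nbr][node_id]
                del adj[node_id]
                del nodes[node_id]
                changed = True
            elif deg == 2:
                (a, ca), (b, cb) = adj[node_id].items()
                del adj[a][node_id]
                del adj[b][node_id]
                del adj[node_id]
                del nodes[node_id]
                # parallel edges cannot arise in a tree
                adj[a][b] = ca + cb
                adj[b][a] = ca + cb
                changed = True
    out = LineageTree(nodes, [])
    done = set()
    for u in adj:
        for v, c in adj[u].items():
            if (v, u) not in done:
                out.edges.append((u, v, c))
                done.add((u, v))
    return out


def root_by_reference(
    tree: LineageTree,
    reference: CellSequence,
    model: CostModel = DEFAULT_COST_MODEL,
) -> RootedLineageTree:
    """Root at the sample whose sequence cost to the reference genotype is
    minimal; ties go to the sample appearing first in the tree."""
    best = None
    for node_id, (kind, seq) in tree.nodes.items():
        if kind != SAMPLE:
            continue
        if seq is None:
            raise ValueError("cannot root a tree without sample sequences")
        d = model.sequence_cost(seq, reference)
        if best is None or d < best[0] - 1e-15:
            best = (d, node_id)
    if best is None:
        raise ValueError("tree has no samples")
    return RootedLineageTree(tree, best[1])


# -- Newick --------------------------------------------------------------

_NEWICK_META = set("();:,[]' \t\n")


def _quote(label: str) -> str:
    if any(ch in _NEWICK_META for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_len(x: float) -> str:
    return format(float(x), ".12g")


def to_newick(tree_or_rooted) -> str:
    """Serialize to Newick with branch lengths equal to edge costs.

    Unrooted trees are anchored at the highest-degree inferred node (ties:
    lexicographically smallest id).  If the tree has no inferred node the
    first sample anchors it and is written as an extra zero-length leaf so
    that leaf path lengths survive the round trip.  Sample nodes that sit at
    internal positions are written as internal node labels.
    """
    if isinstance(tree_or_rooted, RootedLineageTree):
        tree, root = tree_or_rooted.tree, tree_or_rooted.root
        anchor_as_leaf = False
    else:
        tree = tree_or_rooted
        inferred = tree.inferred_ids
        if inferred:
            root = max(inferred, key=lambda n: (tree.degree(n), n))
            # ties: prefer smallest id among max-degree
            maxdeg = tree.degree(root)
            root = min(n for n in inferred if tree.degree(n) == maxdeg)
            anchor_as_leaf = False
        else:
            root = sorted(tree.sample_ids)[0]
            anchor_as_leaf = True
    if len(tree.nodes) == 1:
        only = next(iter(tree.nodes))
        return f"{_quote(only)};"
    adj = tree.adjacency()

    def render(node: str, parent: Optional[str]) -> str:
        children = [n for n in adj[node] if n != parent]
        label = _quote(node)
        if not children:
            return label
        inner = ",".join(
            render(ch, node) + ":" + _fmt_len(adj[node][ch]) for ch in children
        )
        return f"({inner}){label}"

    if anchor_as_leaf:
        # unlabeled root: anchor's neighbor subtrees plus the anchor itself at length 0
        inner = ",".join(
            render(ch, root) + ":" + _fmt_len(adj[root][ch]) for ch in adj[root]
        )
        return f"({inner},{_quote(root)}:0);"
    return render(root, None) + ";"


def from_newick(text: str) -> LineageTree:
    """Parse Newick into a LineageTree (no sequences).

    Labeled nodes become samples; unlabeled nodes and nodes whose label
    starts with ``node`` or ``clone:`` (the writer's conventions for
    inferred ancestors and clone nodes) become inferred ancestors.
    """
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)
    tree = LineageTree()
    names: Dict[int, str] = {}
    counter = [0]
    for nd in dt.preorder_node_iter():
        label = nd.taxon.label if nd.taxon is not None else nd.label
        if label is None or label.startswith("node") or label.startswith("clone:"):
            if label is None:
                label = f"node{counter[0]}"
                counter[0] += 1
            kind = INFERRED
        else:
            kind = SAMPLE
        if label in tree.nodes:  # defensive: disambiguate duplicates
            label = f"{label}#{counter[0]}"
            counter[0] += 1
        names[id(nd)] = label
        tree.add_node(label, kind)
    for nd in dt.preorder_node_iter():
        if nd.parent_node is not None:
            c = nd.edge.length if nd.edge.length is not None else 0.0
            tree.add_edge(names[id(nd.parent_node)], names[id(nd)], float(c))
    return tree
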