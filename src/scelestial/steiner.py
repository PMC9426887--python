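"""k-restricted Steiner-tree approximation for lineage inference.

The inference problem: given n observed cell genotypes, find a minimum-cost
tree that contains them all, where extra (inferred, ancestral) genotypes may
be added as branching points and edge costs are summed per-locus
substitution costs.  Conceptually this is a Steiner tree problem in the
(never materialized) graph of all length-m genotype sequences.

The approximation scheme maintains a minimum spanning tree M over the
samples and repeatedly tries to improve it with small "full components":
for every subset K of at most k samples and every unrooted leaf-labeled
topology on K, a per-locus dynamic program finds the best internal
(ancestral) genotypes.  If grafting that candidate component beats the
costliest spanning-tree edges it can replace (the *bridges*), the exchange
is recorded and M is updated with discounted replacement edges.  A
stack-based screening pass then keeps a loop-free subset of the recorded
candidates, which are merged and completed into the final lineage tree.
With k=3 the result is within 11/6 of the optimum on missing-free two-state
data, and within 16/9 for k=4.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .cost import CostModel, DEFAULT_COST_MODEL
from .genotype import MISSING, N_OBSERVED, CellSequence, GenotypeMatrix
from .tree import INFERRED, SAMPLE, LineageTree, collapse_redundant, impute_missing

__all__ = [
    "SpanningTree",
    "Topology",
    "CandidateTree",
    "build_mst",
    "enumerate_topologies",
    "optimal_internal_sequences",
    "find_bridges",
    "examination_phase",
    "evaluation_phase",
    "application_phase",
    "run_scelestial",
    "restricted_steiner_ratio",
    "exact_steiner_oracle",
]

ORIGINAL = "original"
REPLACEMENT = "replacement"


def _norm_edge(u: int, v: int) -> Tuple[int, int]:
    return (u, v) if u < v else (v, u)


class SpanningTree:
    """Mutable spanning tree over sample indices 0..n-1.

    Edges carry a cost and an origin tag: ``original`` edges cost the
    sequence cost of their endpoints; ``replacement`` edges carry the
    discounted costs assigned during the examination phase.
    """

    def __init__(self, n: int):
        self.n = n
        self.adj: Dict[int, Dict[int, Tuple[float, str]]] = {i: {} for i in range(n)}

    def add_edge(self, u: int, v: int, cost: float, origin: str = ORIGINAL):
        if v in self.adj[u]:
            raise ValueError(f"edge {u}-{v} already present")
        self.adj[u][v] = (cost, origin)
        self.adj[v][u] = (cost, origin)

    def remove_edge(self, u: int, v: int):
        del self.adj[u][v]
        del self.adj[v][u]

    def edges(self) -> List[Tuple[int, int, float, str]]:
        out = []
        for u in range(self.n):
            for v, (c, o) in self.adj[u].items():
                if u < v:
                    out.append((u, v, c, o))
        return out

    def n_edges(self) -> int:
        return sum(len(d) for d in self.adj.values()) // 2

    def total_cost(self) -> float:
        return sum(c for _, _, c, _ in self.edges())

    def is_spanning_tree(self) -> bool:
        if self.n_edges() != self.n - 1:
            return False
        seen = {0}
        stack = [0]
        while stack:
            x = stack.pop()
            for y in self.adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return len(seen) == self.n

    def copy(self) -> "SpanningTree":
        out = SpanningTree(self.n)
        for u in range(self.n):
            out.adj[u] = dict(self.adj[u])
        return out


def build_mst(sequences: Sequence[CellSequence], model: CostModel = DEFAULT_COST_MODEL) -> SpanningTree:
    """Minimum spanning tree over the samples under the sequence cost.

    Kruskal with deterministic tie-breaking by (cost, min endpoint,
    max endpoint).
    """
    n = len(sequences)
    if n == 0:
        raise ValueError("need at least one sequence")
    states = np.column_stack([s.states for s in sequences]) if n > 0 else None
    costs = model.pairwise_costs(states)
    tree = SpanningTree(n)
    if n == 1:
        return tree
    order = sorted(
        ((costs[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
    )
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    added = 0
    for c, i, j in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.add_edge(i, j, float(c), ORIGINAL)
            added += 1
            if added == n - 1:
                break
    return tree


@dataclass(frozen=True)
class Topology:
    """Unrooted leaf-labeled tree shape: leaves 0..L-1, internal nodes
    L..L+I-1, every internal node of degree 3."""

    n_leaves: int
    n_internal: int
    edges: Tuple[Tuple[int, int], ...]

    def internal_ids(self):
        return range(self.n_leaves, self.n_leaves + self.n_internal)


@lru_cache(maxsize=None)
def enumerate_topologies(n_leaves: int) -> Tuple[Topology, ...]:
    """All distinct unrooted binary topologies on labeled leaves.

    Count is (2L-5)!! for L >= 3 and 1 for L = 2; generated by inserting
    leaf L-1 into every edge of every (L-1)-leaf topology.
    """
    L = n_leaves
    if L < 2:
        raise ValueError("need at least 2 leaves")
    if L == 2:
        return (Topology(2, 0, ((0, 1),)),)
    if L == 3:
        return (Topology(3, 1, ((0, 3), (1, 3), (2, 3))),)
    out = []
    for base in enumerate_topologies(L - 1):
        # renumber base internals: leaf ids stay 0..L-2, internals shift by 1
        shift = 1  # new leaf gets id L-1, old internal i -> i+1
        def ren(x):
            return x if x < L - 1 else x + shift
        base_edges = [(ren(a), ren(b)) for a, b in base.edges]
        new_internal = L + base.n_internal  # fresh internal node id
        for idx in range(len(base_edges)):
            a, b = base_edges[idx]
            edges = list(base_edges)
            del edges[idx]
            edges.extend([(a, new_internal), (b, new_internal), (L - 1, new_internal)])
            out.append(Topology(L, base.n_internal + 1, tuple(sorted(_norm_edge(*e) for e in edges))))
    return tuple(out)


def _rooted_orders(topology: Topology):
    """Postorder node list and parent map, rooted at the first internal node."""
    L = topology.n_leaves
    root = L
    adj: Dict[int, List[int]] = {}
    for a, b in topology.edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    parent = {root: None}
    order = []
    stack = [root]
    while stack:
        x = stack.pop()
        order.append(x)
        for y in adj[x]:
            if y != parent[x]:
                parent[y] = x
                stack.append(y)
    return order[::-1], parent  # postorder (children before parents)


def _sankoff(
    leafcosts: np.ndarray,
    topology: Topology,
    trans: np.ndarray,
    backtrack: bool = False,
):
    """Per-locus small-parsimony DP on a fixed topology.

    ``leafcosts[i]`` is an (m, S) array: cost of attaching leaf i to an
    adjacent internal node in each internal state (rows = loci).  ``trans``
    is the (S, S) internal-internal substitution cost.  Internal states
    range over observed genotypes only — the DP never assigns a missing
    state — and every tie in a minimization resolves to the lowest state
    code, making the inferred ancestors fully deterministic.

    Returns the minimum total cost, plus per-internal-node state arrays
    when ``backtrack`` is set.
    """
    L, I = topology.n_leaves, topology.n_internal
    if I == 1:
        # star: one internal node adjacent to every leaf
        total = leafcosts.sum(axis=0)  # (m, S)
        if not backtrack:
            return float(total.min(axis=1).sum())
        states = total.argmin(axis=1)
        return float(total.min(axis=1).sum()), {topology.n_leaves: states}
    order, parent = _rooted_orders(topology)
    msg: Dict[int, np.ndarray] = {}
    subtree: Dict[int, np.ndarray] = {}
    for node in order:
        if node < L:
            msg[node] = leafcosts[node]
            continue
        children = [x for x in msg if parent.get(x) == node]
        d = sum(msg[x] for x in children)
        subtree[node] = d
        if parent[node] is not None:
            # message to parent: min over own state s' of d[:, s'] + trans[s', s]
            msg[node] = (d[:, :, None] + trans[None, :, :]).min(axis=1)
    root = L
    cost = float(subtree[root].min(axis=1).sum())
    if not backtrack:
        return cost
    assign: Dict[int, np.ndarray] = {root: subtree[root].argmin(axis=1)}
    for node in reversed(order):  # preorder
        if node < L or node == root:
            continue
        p_states = assign[parent[node]]
        m = subtree[node].shape[0]
        assign[node] = (subtree[node] + trans[:, p_states].T).argmin(axis=1)
    return cost, assign


def _leafcost_tensor(sequences: Sequence[CellSequence], model: CostModel) -> np.ndarray:
    """(n, m, 10) attachment-cost tensor: entry [i, t, s] is the cost of
    locus t of sample i against observed internal state s."""
    obs = model.observed_table  # (11, 10)
    return np.stack([obs[s.states] for s in sequences])


def optimal_internal_sequences(
    K_seqs: Sequence[CellSequence],
    topology: Topology,
    model: CostModel = DEFAULT_COST_MODEL,
) -> Tuple[List[CellSequence], float]:
    """Best missing-free internal genotypes for a fixed topology, plus the
    resulting tree cost (minimum over all internal assignments)."""
    if len(K_seqs) != topology.n_leaves:
        raise ValueError("leaf count does not match topology")
    if topology.n_internal == 0:
        cost = model.sequence_cost(K_seqs[0], K_seqs[1])
        return [], cost
    leafcosts = _leafcost_tensor(K_seqs, model)
    trans = model.table[:N_OBSERVED, :N_OBSERVED]
    cost, assign = _sankoff(leafcosts, topology, trans, backtrack=True)
    internals = [
        CellSequence(f"internal{i - topology.n_leaves}", assign[i].astype(np.int8))
        for i in topology.internal_ids()
    ]
    return internals, cost


@dataclass
class CandidateTree:
    """A candidate full component recorded during the examination phase."""

    terminals: Tuple[int, ...]
    topology: Topology
    tree_cost: float
    bridges: List[Tuple[int, int, float]]
    gain: float
    internal_sequences: Optional[List[CellSequence]] = None


def find_bridges(
    M: SpanningTree, K: Sequence[int]
) -> Tuple[List[Tuple[int, int, float]], List[Tuple[int, int]]]:
    """Maximum-cost set of |K|-1 spanning-tree edges whose removal splits M
    into components holding one terminal of K each.

    Computed greedily: repeatedly remove the costliest M-edge lying on a
    path between two terminals not yet separated (an exchange argument
    shows the greedy set has maximum total cost among all valid sets).
    Also returns, per bridge, the pair of terminals whose components the
    bridge connected — the endpoints of its replacement edge.
    """
    K = sorted(set(K))
    if len(K) < 2:
        raise ValueError("need at least two terminals")
    for t in K:
        if not (0 <= t < M.n):
            raise ValueError(f"terminal {t} not a node of the spanning tree")
    removed: set = set()
    bridges: List[Tuple[int, int, float]] = []

    def components():
        """comp id per node, BFS parents, skipping removed edges."""
        comp = {}
        parents = {}
        cid = 0
        for start in K:
            if start in comp:
                continue
            comp[start] = cid
            parents[start] = None
            stack = [start]
            while stack:
                x = stack.pop()
                for y in M.adj[x]:
                    if _norm_edge(x, y) in removed or y in comp:
                        continue
                    comp[y] = cid
                    parents[y] = x
                    stack.append(y)
            cid += 1
        return comp, parents

    for _ in range(len(K) - 1):
        comp, parents = components()
        groups: Dict[int, List[int]] = {}
        for t in K:
            groups.setdefault(comp[t], []).append(t)
        best = None  # (cost, (u, v))
        for ts in groups.values():
            if len(ts) < 2:
                continue
            # union of parent-chain paths from each terminal to the BFS root
            # is the minimal subtree of the component spanning its terminals
            seen_edges = set()
            for t in ts[1:] + ts[:1]:
                x = t
                while parents[x] is not None:
                    e = _norm_edge(x, parents[x])
                    if e in seen_edges:
                        break
                    seen_edges.add(e)
                    x = parents[x]
            # restrict to edges actually between terminal-containing parts:
            # an edge is on a terminal-terminal path iff both sides of it
            # contain a terminal; pruning: repeatedly drop leaf edges of the
            # collected subtree whose leaf end is not a terminal.
            sub_adj: Dict[int, set] = {}
            for a, b in seen_edges:
                sub_adj.setdefault(a, set()).add(b)
                sub_adj.setdefault(b, set()).add(a)
            term_set = set(ts)
            changed = True
            while changed:
                changed = False
                for x in list(sub_adj):
                    if len(sub_adj[x]) == 1 and x not in term_set:
                        (y,) = sub_adj[x]
                        sub_adj[y].discard(x)
                        del sub_adj[x]
                        changed = True
            for a in sub_adj:
                for b in sub_adj[a]:
                    if a < b:
                        c = M.adj[a][b][0]
                        if best is None or c > best[0] or (c == best[0] and (a, b) < best[1]):
                            best = (c, (a, b))
        if best is None:  # pragma: no cover - defensive
            raise RuntimeError("terminals already separated; invalid state")
        removed.add(best[1])
        bridges.append((best[1][0], best[1][1], best[0]))

    comp, _ = components()
    term_of_comp = {comp[t]: t for t in K}
    pairing = [(term_of_comp[comp[a]], term_of_comp[comp[b]]) for a, b, _ in bridges]
    return bridges, pairing


def examination_phase(
    sequences: Sequence[CellSequence],
    model: CostModel = DEFAULT_COST_MODEL,
    k: int = 3,
    gain_threshold: float = 0.0,
    M: Optional[SpanningTree] = None,
    stack: Optional[List[CandidateTree]] = None,
) -> Tuple[List[CandidateTree], SpanningTree]:
    """Scan all sample subsets (sizes 3..k, ascending, lexicographic) and
    all topologies; record every candidate whose gain over its bridges
    exceeds the threshold, exchanging the bridges for discounted
    replacement edges in M as it goes.

    Pair subsets are skipped: a bare edge between two samples can never
    beat the path already connecting them in M (its gain is <= 0).
    """
    n = len(sequences)
    if n == 0:
        raise ValueError("need at least one sequence")
    if k < 3:
        raise ValueError("k must be at least 3")
    if M is None:
        M = build_mst(sequences, model)
    if stack is None:
        stack = []
    if n < 3:
        return stack, M
    leafcosts = _leafcost_tensor(sequences, model)
    trans = model.table[:N_OBSERVED, :N_OBSERVED]
    for size in range(3, min(k, n) + 1):
        topologies = enumerate_topologies(size)
        for K in itertools.combinations(range(n), size):
            lc = leafcosts[list(K)]
            for tau in topologies:
                tree_cost = _sankoff(lc, tau, trans)
                bridges, pairing = find_bridges(M, K)
                gain = sum(c for _, _, c in bridges) - tree_cost
                if gain > gain_threshold:
                    stack.append(CandidateTree(tuple(K), tau, tree_cost, bridges, gain))
                    for (a, b, c), (tu, tv) in zip(bridges, pairing):
                        M.remove_edge(a, b)
                    for (a, b, c), (tu, tv) in zip(bridges, pairing):
                        M.add_edge(tu, tv, c - gain, REPLACEMENT)
    return stack, M


def evaluation_phase(stack: List[CandidateTree]) -> List[CandidateTree]:
    """Pop candidates LIFO; accept one iff its terminals still lie in
    pairwise-distinct components of the accepted set, then merge them."""
    parent: Dict[int, int] = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    accepted = []
    for cand in reversed(stack):
        roots = {find(t) for t in cand.terminals}
        if len(roots) == len(cand.terminals):
            accepted.append(cand)
            it = iter(roots)
            first = next(it)
            for r in it:
                parent[r] = first
    return accepted


def application_phase(
    accepted: List[CandidateTree],
    sequences: Sequence[CellSequence],
    model: CostModel = DEFAULT_COST_MODEL,
) -> LineageTree:
    """Merge the accepted components and complete them into one spanning
    lineage tree with original pairwise edges in increasing cost order."""
    n = len(sequences)
    ids = [s.sample_id for s in sequences]
    if len(set(ids)) != n:
        raise ValueError("sample ids must be unique")
    tree = LineageTree()
    for s in sequences:
        tree.add_node(s.sample_id, SAMPLE, s)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node_counter = 0
    for cand in accepted:
        K_seqs = [sequences[i] for i in cand.terminals]
        if cand.topology.n_internal == 0:
            c = model.sequence_cost(K_seqs[0], K_seqs[1])
            tree.add_edge(ids[cand.terminals[0]], ids[cand.terminals[1]], c)
        else:
            internals, _ = optimal_internal_sequences(K_seqs, cand.topology, model)
            cand.internal_sequences = internals
            local: Dict[int, str] = {}
            for li, t in enumerate(cand.terminals):
                local[li] = ids[t]
            seq_of: Dict[int, CellSequence] = {
                li: sequences[t] for li, t in enumerate(cand.terminals)
            }
            for j, iseq in zip(cand.topology.internal_ids(), internals):
                nid = f"node{node_counter}"
                node_counter += 1
                tree.add_node(nid, INFERRED, CellSequence(nid, iseq.states))
                local[j] = nid
                seq_of[j] = iseq
            for a, b in cand.topology.edges:
                tree.add_edge(local[a], local[b], model.sequence_cost(seq_of[a], seq_of[b]))
        it = iter(cand.terminals)
        first = find(next(it))
        for t in it:
            parent[find(t)] = first
    if n > 1:
        states = np.column_stack([s.states for s in sequences])
        costs = model.pairwise_costs(states)
        order = sorted((costs[i, j], i, j) for i in range(n) for j in range(i + 1, n))
        for c, i, j in order:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                tree.add_edge(ids[i], ids[j], float(c))
    tree.validate()
    return tree


def run_scelestial(
    matrix,
    k: int = 3,
    model: CostModel = DEFAULT_COST_MODEL,
    gain_threshold: float = 0.0,
    passes: int = 1,
    impute: bool = True,
    collapse: bool = True,
) -> LineageTree:
    """Full inference: MST init, examination/evaluation/application, then
    imputation of missing sample loci and suppression of redundant inferred
    nodes.  Deterministic given its inputs.

    ``matrix`` may be a :class:`GenotypeMatrix` or a list of
    :class:`CellSequence`.
    """
    if isinstance(matrix, GenotypeMatrix):
        sequences = matrix.sequences()
    else:
        sequences = list(matrix)
    n = len(sequences)
    if n == 0:
        raise ValueError("need at least one sample")
    if n == 1:
        tree = LineageTree()
        tree.add_node(sequences[0].sample_id, SAMPLE, sequences[0])
        return impute_missing(tree, model) if impute else tree
    M = build_mst(sequences, model)
    stack: List[CandidateTree] = []
    for _ in range(max(1, passes)):
        stack, M = examination_phase(
            sequences, model, k=k, gain_threshold=gain_threshold, M=M, stack=stack
        )
    accepted = evaluation_phase(stack)
    tree = application_phase(accepted, sequences, model)
    if impute:
        tree = impute_missing(tree, model)
    if collapse:
        tree = collapse_redundant(tree)
    return tree


def restricted_steiner_ratio(k: int) -> float:
    """Worst-case ratio of the best k-restricted Steiner tree to the true
    optimum: with k = 2**r + s, 0 <= s < 2**r, the ratio is
    (r*2**r + s) / ((r+1)*2**r + s)."""
    if k < 2:
        raise ValueError("k must be at least 2")
    r = k.bit_length() - 1
    s = k - (1 << r)
    return (r * (1 << r) + s) / ((r + 1) * (1 << r) + s)


def exact_steiner_oracle(
    sequences: Sequence[CellSequence],
    model: CostModel = DEFAULT_COST_MODEL,
    max_loci: int = 6,
    max_terminals: int = 7,
) -> float:
    """Exact minimum Steiner-tree cost for small missing-free instances.

    The candidate vertex set is the product, over loci, of the states
    observed at that locus (at most two per locus — binary data), which is
    sufficient: any internal state can be replaced per-locus by an observed
    one without increasing cost.  Solved by the Dreyfus–Wagner dynamic
    program over (terminal subset, vertex) pairs.  Independent of the
    approximation pipeline; used as a test oracle.
    """
    seqs = list(sequences)
    if not seqs:
        raise ValueError("need at least one sequence")
    m = len(seqs[0])
    if m > max_loci:
        raise ValueError(f"instance too large: {m} loci > {max_loci}")
    grid = np.stack([s.states for s in seqs])  # (n, m)
    if np.any(grid == MISSING):
        raise ValueError("oracle requires missing-free sequences")
    per_locus = [sorted(set(int(x) for x in grid[:, t])) for t in range(m)]
    if any(len(p) > 2 for p in per_locus):
        raise ValueError("oracle requires at most two observed states per locus")
    vertices = list(itertools.product(*per_locus))
    n_v = len(vertices)
    vindex = {v: i for i, v in enumerate(vertices)}
    terminals = sorted({vindex[tuple(int(x) for x in row)] for row in grid})
    if len(terminals) > max_terminals:
        raise ValueError(f"instance too large: {len(terminals)} terminals > {max_terminals}")
    if len(terminals) == 1:
        return 0.0
    varr = np.array(vertices)  # (n_v, m)
    table = model.table
    dist = np.zeros((n_v, n_v))
    for t in range(m):
        dist += table[varr[:, t]][:, varr[:, t]]
    t0, rest = terminals[0], terminals[1:]
    q = len(rest)
    full = (1 << q) - 1
    INF = math.inf
    S = np.full((1 << q, n_v), INF)
    for i, t in enumerate(rest):
        S[1 << i] = dist[t]
    masks = sorted(range(1, full + 1), key=lambda mk: bin(mk).count("1"))
    for mask in masks:
        if bin(mask).count("1") < 2:
            continue
        merge = np.full(n_v, INF)
        sub = (mask - 1) & mask
        while sub:
            other = mask ^ sub
            if sub < other:
                np.minimum(merge, S[sub] + S[other], out=merge)
            sub = (sub - 1) & mask
        best = np.minimum(S[mask], merge)
        S[mask] = (best[:, None] + dist).min(axis=0)
    return float(S[full][t0])
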