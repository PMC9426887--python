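import itertools

import numpy as np
import pytest

from scelestial.cost import CostModel
from scelestial.genotype import MISSING, N_OBSERVED, CellSequence
from scelestial.steiner import (
    CandidateTree,
    SpanningTree,
    Topology,
    application_phase,
    build_mst,
    enumerate_topologies,
    evaluation_phase,
    examination_phase,
    exact_steiner_oracle,
    find_bridges,
    optimal_internal_sequences,
    restricted_steiner_ratio,
    run_scelestial,
)
from scelestial.tree import to_newick
from conftest import random_sequences

MODEL = CostModel()


# ---------------------------------------------------------------- oracles
def brute_force_mst_cost(seqs, model):
    """Minimum total cost over all labeled spanning trees (Pruefer)."""
    n = len(seqs)
    costs = model.pairwise_costs(np.column_stack([s.states for s in seqs]))
    if n == 2:
        return costs[0, 1]
    best = np.inf
    for prufer in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for x in prufer:
            degree[x] += 1
        total = 0.0
        deg = list(degree)
        leaves = sorted(i for i in range(n) if deg[i] == 1)
        for x in prufer:
            leaf = leaves.pop(0)
            total += costs[leaf, x]
            deg[x] -= 1
            if deg[x] == 1:
                import bisect

                bisect.insort(leaves, x)
        u, v = leaves
        total += costs[u, v]
        best = min(best, total)
    return best


def brute_force_bridges_cost(M, K):
    """Max-cost edge subset whose removal leaves one terminal per component."""
    edges = [(u, v, c) for u, v, c, _ in M.edges()]
    K = sorted(set(K))
    best = None
    for combo in itertools.combinations(range(len(edges)), len(K) - 1):
        removed = {(edges[i][0], edges[i][1]) for i in combo}
        comp = {}
        cid = 0
        for start in range(M.n):
            if start in comp:
                continue
            comp[start] = cid
            stack = [start]
            while stack:
                x = stack.pop()
                for y in M.adj[x]:
                    e = (x, y) if x < y else (y, x)
                    if e in removed or y in comp:
                        continue
                    comp[y] = cid
                    stack.append(y)
            cid += 1
        terms_per_comp = {}
        for t in K:
            terms_per_comp.setdefault(comp[t], []).append(t)
        if len(terms_per_comp) == len(K) and all(
            len(v) == 1 for v in terms_per_comp.values()
        ):
            cost = sum(edges[i][2] for i in combo)
            if best is None or cost > best:
                best = cost
    return best


def brute_force_internal_cost(leaf_states, topology, model):
    """Exhaustive minimum over all internal-state assignments, per locus."""
    table = model.table
    m = leaf_states.shape[1]
    I = topology.n_internal
    total = 0.0
    for t in range(m):
        best = np.inf
        for assign in itertools.product(range(N_OBSERVED), repeat=I):
            state = {}
            for leaf in range(topology.n_leaves):
                state[leaf] = leaf_states[leaf, t]
            for j, s in zip(topology.internal_ids(), assign):
                state[j] = s
            cost = sum(table[state[a], state[b]] for a, b in topology.edges)
            best = min(best, cost)
        total += best
    return total


def random_spanning_tree(rng, n):
    M = SpanningTree(n)
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[int(rng.integers(0, i))]
        M.add_edge(int(order[i]), int(j), float(rng.integers(1, 20)))
    return M


# ---------------------------------------------------------------- topologies
class TestTopologies:
    @pytest.mark.parametrize("L,count", [(2, 1), (3, 1), (4, 3), (5, 15), (6, 105)])
    def test_double_factorial_count(self, L, count):
        topos = enumerate_topologies(L)
        assert len(topos) == count
        assert len(set(t.edges for t in topos)) == count

    def test_internal_degree_three(self):
        for topo in enumerate_topologies(5):
            deg = {}
            for a, b in topo.edges:
                deg[a] = deg.get(a, 0) + 1
                deg[b] = deg.get(b, 0) + 1
            for leaf in range(5):
                assert deg[leaf] == 1
            for j in topo.internal_ids():
                assert deg[j] == 3

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            enumerate_topologies(1)


# ---------------------------------------------------------------- MST
class TestMST:
    def test_worked_example_matches_brute_force(self, worked_sequences):
        M = build_mst(worked_sequences, MODEL)
        eps = MODEL.epsilon
        assert M.total_cost() == pytest.approx(3.5 + 3 * eps, abs=1e-12)
        assert M.total_cost() == pytest.approx(
            brute_force_mst_cost(worked_sequences, MODEL), abs=1e-12
        )
        # the missing-bearing cell is the cheap hub
        hub_edges = {tuple(sorted((u, v))) for u, v, _, _ in M.edges()}
        assert hub_edges == {(0, 3), (1, 3), (2, 3)}

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_random_instances_match_brute_force(self, n, rng):
        for _ in range(10):
            seqs = random_sequences(rng, n, 4, missing_rate=0.2)
            M = build_mst(seqs, MODEL)
            assert M.is_spanning_tree()
            assert M.total_cost() == pytest.approx(
                brute_force_mst_cost(seqs, MODEL), abs=1e-9
            )

    def test_degenerate_sizes(self, rng):
        (s,) = random_sequences(rng, 1, 3)
        assert build_mst([s], MODEL).n_edges() == 0
        s1, s2 = random_sequences(rng, 2, 3)
        M = build_mst([s1, s2], MODEL)
        assert M.n_edges() == 1
        assert M.total_cost() == MODEL.sequence_cost(s1, s2)
        with pytest.raises(ValueError):
            build_mst([], MODEL)


# ---------------------------------------------------------------- DP
class TestInternalSequenceDP:
    def test_worked_star(self):
        from scelestial.genotype import sequences_from_strings, state_to_token

        seqs = sequences_from_strings(["CAC", "GAG", "GCC"])
        (topo,) = enumerate_topologies(3)
        internals, cost = optimal_internal_sequences(seqs, topo, MODEL)
        assert cost == pytest.approx(3.0, abs=1e-12)
        tokens = [state_to_token(int(s))[0] for s in internals[0].states]
        assert tokens == ["G", "A", "C"]

    def test_identical_leaves_on_bare_edge(self, rng):
        (s,) = random_sequences(rng, 1, 4)
        twin = CellSequence("twin", s.states.copy())
        topo = enumerate_topologies(2)[0]
        internals, cost = optimal_internal_sequences([s, twin], topo, MODEL)
        assert internals == [] and cost == 0.0

    def test_missing_leaf_locus_contributes_half_plus_epsilon(self):
        from scelestial.genotype import sequences_from_strings

        seqs = sequences_from_strings(["XAA", "AAA", "AAA"])
        (topo,) = enumerate_topologies(3)
        _, cost = optimal_internal_sequences(seqs, topo, MODEL)
        assert cost == pytest.approx(0.5 + MODEL.epsilon, abs=1e-12)

    @pytest.mark.parametrize("L", [2, 3, 4])
    @pytest.mark.parametrize("missing_rate", [0.0, 0.3])
    def test_matches_exhaustive_enumeration(self, L, missing_rate, rng):
        for topo in enumerate_topologies(L):
            for _ in range(8):
                m = int(rng.integers(1, 4))
                seqs = random_sequences(rng, L, m, missing_rate=missing_rate)
                internals, cost = optimal_internal_sequences(seqs, topo, MODEL)
                leaf_states = np.stack([s.states for s in seqs])
                assert cost == pytest.approx(
                    brute_force_internal_cost(leaf_states, topo, MODEL), abs=1e-9
                )
                for seq in internals:
                    assert not seq.has_missing()

    def test_per_locus_decomposability(self, rng):
        # total DP cost equals the sum of single-locus DP costs
        for topo in enumerate_topologies(4):
            seqs = random_sequences(rng, 4, 5, missing_rate=0.2)
            _, cost = optimal_internal_sequences(seqs, topo, MODEL)
            per_locus = 0.0
            for t in range(5):
                sub = [CellSequence(s.sample_id, s.states[t : t + 1]) for s in seqs]
                _, c = optimal_internal_sequences(sub, topo, MODEL)
                per_locus += c
            assert cost == pytest.approx(per_locus, abs=1e-9)


# ---------------------------------------------------------------- bridges
class TestBridges:
    def test_pair_takes_max_edge_on_path(self, rng):
        M = random_spanning_tree(rng, 6)
        bridges, pairing = find_bridges(M, [0, 1])
        assert len(bridges) == 1
        assert bridges[0][2] == brute_force_bridges_cost(M, [0, 1])
        assert set(pairing[0]) == {0, 1}

    @pytest.mark.parametrize("ksize", [2, 3, 4])
    def test_matches_brute_force(self, ksize, rng):
        for _ in range(20):
            n = int(rng.integers(ksize + 1, 9))
            M = random_spanning_tree(rng, n)
            K = sorted(rng.choice(n, size=ksize, replace=False).tolist())
            bridges, pairing = find_bridges(M, K)
            assert len(bridges) == ksize - 1
            assert sum(c for _, _, c in bridges) == pytest.approx(
                brute_force_bridges_cost(M, K), abs=1e-9
            )
            # each replacement pair consists of distinct terminals of K
            for tu, tv in pairing:
                assert tu in K and tv in K and tu != tv

    def test_pendant_terminals_off_hub(self):
        # terminals hanging off one hub: bridges are their costliest pendants
        M = SpanningTree(5)
        costs = {1: 5.0, 2: 7.0, 3: 2.0, 4: 4.0}
        for leaf, c in costs.items():
            M.add_edge(0, leaf, c)
        bridges, _ = find_bridges(M, [1, 2, 3, 4])
        assert sorted(c for _, _, c in bridges) == [4.0, 5.0, 7.0]

    def test_foreign_terminal_rejected(self, rng):
        M = random_spanning_tree(rng, 4)
        with pytest.raises(ValueError):
            find_bridges(M, [0, 99])


# ---------------------------------------------------------------- phases
class TestExaminationPhase:
    def test_m_stays_spanning_tree_and_gains_positive(self, rng):
        for _ in range(10):
            seqs = random_sequences(rng, 8, 6, missing_rate=0.2)
            stack, M = examination_phase(seqs, MODEL, k=3)
            assert M.is_spanning_tree()
            for cand in stack:
                assert cand.gain > 0.0

    def test_replacement_edges_cost_below_bridges(self, rng):
        for _ in range(10):
            seqs = random_sequences(rng, 7, 5, missing_rate=0.1)
            stack, M = examination_phase(seqs, MODEL, k=3)
            for cand in stack:
                for _, _, c in cand.bridges:
                    assert c - cand.gain < c

    def test_small_k_rejected(self, rng):
        with pytest.raises(ValueError):
            examination_phase(random_sequences(rng, 4, 3), MODEL, k=2)


class TestEvaluationPhase:
    def _cand(self, terms):
        topo = enumerate_topologies(len(terms))[0]
        return CandidateTree(tuple(terms), topo, 0.0, [], 1.0)

    def test_empty_stack(self):
        assert evaluation_phase([]) == []

    def test_disjoint_candidates_both_accepted(self):
        stack = [self._cand((0, 1, 2)), self._cand((3, 4, 5))]
        assert len(evaluation_phase(stack)) == 2

    def test_lifo_order_and_loop_rejection(self):
        # top of stack wins; a later pop whose terminals are already merged loses
        stack = [self._cand((0, 1, 2)), self._cand((0, 1, 3))]
        accepted = evaluation_phase(stack)
        assert [c.terminals for c in accepted] == [(0, 1, 3)]

    def test_partially_overlapping_chain(self):
        stack = [self._cand((0, 1, 2)), self._cand((2, 3, 4)), self._cand((4, 5, 6))]
        accepted = evaluation_phase(stack)
        # popped 4-5-6 then 2-3-4 (shares only node 4's component) then 0-1-2
        assert [c.terminals for c in accepted] == [(4, 5, 6), (2, 3, 4), (0, 1, 2)]


class TestApplicationPhase:
    def test_no_candidates_equals_mst(self, rng):
        seqs = random_sequences(rng, 6, 5, missing_rate=0.1)
        tree = application_phase([], seqs, MODEL)
        assert tree.total_cost() == pytest.approx(
            build_mst(seqs, MODEL).total_cost(), abs=1e-9
        )
        assert not tree.inferred_ids

    def test_single_triple_covering_all_samples(self):
        from scelestial.genotype import sequences_from_strings

        seqs = sequences_from_strings(["CAC", "GAG", "GCC"])
        (topo,) = enumerate_topologies(3)
        cand = CandidateTree((0, 1, 2), topo, 3.0, [], 1.0)
        tree = application_phase([cand], seqs, MODEL)
        assert len(tree.inferred_ids) == 1
        assert tree.total_cost() == pytest.approx(3.0, abs=1e-12)

    def test_output_never_beats_nothing_but_mst(self, rng):
        # gain-positive exchanges only: final tree cost <= MST cost
        for _ in range(200):
            n = int(rng.integers(3, 9))
            seqs = random_sequences(rng, n, int(rng.integers(2, 7)), missing_rate=0.15)
            tree = run_scelestial(seqs, k=3, impute=False, collapse=False)
            assert tree.total_cost() <= build_mst(seqs, MODEL).total_cost() + 1e-9


# ---------------------------------------------------------------- ratios & oracle
class TestRestrictedSteinerRatio:
    @pytest.mark.parametrize("k,expected", [(2, 0.5), (3, 3 / 5), (4, 2 / 3)])
    def test_known_values(self, k, expected):
        assert restricted_steiner_ratio(k) == pytest.approx(expected, abs=1e-15)

    def test_monotone_increasing_toward_one(self):
        vals = [restricted_steiner_ratio(k) for k in range(2, 40)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            restricted_steiner_ratio(1)


class TestExactSteinerOracle:
    def test_two_terminals_is_hamming(self, rng):
        for _ in range(10):
            seqs = random_sequences(rng, 2, 5, n_states=2)
            assert exact_steiner_oracle(seqs, MODEL) == MODEL.sequence_cost(*seqs)

    def test_median_vertex_instance(self):
        from scelestial.genotype import sequences_from_strings

        seqs = sequences_from_strings(["AA", "AC", "CA"])
        assert exact_steiner_oracle(seqs, MODEL) == pytest.approx(2.0)

    def test_matches_exhaustive_vertex_subset_search(self, rng):
        # independent check: min over vertex subsets of the MST on terminals+subset
        from scipy.sparse.csgraph import minimum_spanning_tree

        for _ in range(6):
            seqs = random_sequences(rng, 3, 3, n_states=2)
            m = 3
            vertices = list(itertools.product(range(2), repeat=m))
            coded = [tuple(int(x) for x in s.states) for s in seqs]
            term_idx = sorted({vertices.index(c) for c in coded})
            dist = np.array(
                [[sum(a != b for a, b in zip(u, v)) for v in vertices] for u in vertices],
                dtype=float,
            )
            best = np.inf
            extra = [i for i in range(len(vertices)) if i not in term_idx]
            for r in range(len(extra) + 1):
                for combo in itertools.combinations(extra, r):
                    chosen = term_idx + list(combo)
                    sub = dist[np.ix_(chosen, chosen)]
                    cost = minimum_spanning_tree(sub).sum()
                    best = min(best, cost)
            # binary states: costs coincide with Hamming distances
            model_opt = exact_steiner_oracle(seqs, MODEL)
            assert model_opt == pytest.approx(best, abs=1e-9)

    def test_oversized_instances_rejected(self, rng):
        with pytest.raises(ValueError):
            exact_steiner_oracle(random_sequences(rng, 2, 9, n_states=2), MODEL)
        eight = [
            CellSequence(f"s{i}", np.array(bits, dtype=np.int8))
            for i, bits in enumerate(itertools.product((0, 1), repeat=3))
        ]
        with pytest.raises(ValueError):
            exact_steiner_oracle(eight, MODEL, max_terminals=7)
        with pytest.raises(ValueError):
            exact_steiner_oracle(random_sequences(rng, 3, 3, missing_rate=0.9), MODEL)


# ---------------------------------------------------------------- end to end
class TestRunScelestial:
    def test_single_and_pair(self, rng):
        (s,) = random_sequences(rng, 1, 4)
        tree = run_scelestial([s])
        assert len(tree.nodes) == 1 and not tree.edges
        s1, s2 = random_sequences(rng, 2, 4)
        tree = run_scelestial([s1, s2])
        assert len(tree.edges) == 1

    def test_deterministic(self, rng):
        seqs = random_sequences(rng, 10, 8, missing_rate=0.2)
        t1 = run_scelestial(seqs, k=3)
        t2 = run_scelestial(seqs, k=3)
        assert to_newick(t1) == to_newick(t2)
        assert t1.edges == t2.edges

    def test_samples_all_present_and_tree_valid(self, rng):
        seqs = random_sequences(rng, 12, 6, missing_rate=0.25)
        tree = run_scelestial(seqs, k=3)
        tree.validate()
        assert sorted(tree.sample_ids) == sorted(s.sample_id for s in seqs)
        for node_id in tree.nodes:
            assert not tree.sequence(node_id).has_missing()
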