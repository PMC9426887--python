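"""Synthetic single-cell datasets: tumor-growth and clonal simulators.

Two generators produce (ground-truth tree, clean matrix, noisy observed
matrix) triples in the binary reference/variant coding:

* :func:`simulate_tumor` grows a cell lineage under selection: each new
  node picks its parent with probability proportional to the parent's
  fitness advantage, inherits the parent's advantage plus a uniform
  perturbation, and gains a Poisson number of mutations at uniformly chosen
  loci (binary flips, so back-mutations can occur).  Cells are then sampled
  from the tree weighted by advantage, and sequencing noise is applied.

* :func:`simulate_clonal` builds a uniform random labeled clone tree and
  assigns mutations to its edges under the infinite-sites assumption (every
  locus mutates at most once in the whole tree).  By default every locus is
  placed on one uniformly chosen edge, so the number of mutated loci equals
  the number of sites; an explicit per-edge Poisson mean is also supported.
  Cells are drawn uniformly from the clones.

Sequencing noise flips reference to variant with the false-positive rate,
variant to reference with the false-negative rate (allelic dropout), and
then masks entries to missing.  Default rates (FP 1.5%, FN 10%, missing 7%)
match values observed in real single-cell variant-call data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genotype import MISSING, REF_STATE, VAR_STATE, CellSequence, GenotypeMatrix
from .metrics import clone_tree_to_sample_tree
from .tree import LineageTree

__all__ = [
    "EvolutionNode",
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tumor_evolution",
    "sample_cells",
    "apply_sequencing_noise",
    "simulate_tumor",
    "simulate_clonal",
]

ADVANTAGE_FLOOR = 1e-3


@dataclass
class EvolutionNode:
    id: int
    parent: Optional[int]
    advantage: float
    sequence: np.ndarray  # binary 0/1 vector, length m
    n_new_mutations: int = 0


@dataclass(frozen=True)
class SimulationConfig:
    """Tumor-growth simulation settings.

    Defaults are the standard benchmark conditions: 5 evolutionary nodes,
    50 sampled cells, 200 sites, 20 mutations per edge on average, FP 1.5%,
    FN 10%, missing 7%.
    """

    n_nodes: int = 5
    n_samples: int = 50
    m_sites: int = 200
    mean_mutations_per_edge: float = 20.0
    fp_rate: float = 0.015
    fn_rate: float = 0.10
    missing_rate: float = 0.07
    advantage_step: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be at least 1")
        if self.n_samples < 1 or self.m_sites < 1:
            raise ValueError("need at least one sample and one site")
        for r in (self.fp_rate, self.fn_rate, self.missing_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.mean_mutations_per_edge < 0 or self.advantage_step < 0:
            raise ValueError("mutation mean and advantage step must be nonnegative")


@dataclass
class SimulatedDataset:
    """Ground truth plus clean and noisy observed matrices."""

    ground_truth_tree: LineageTree
    clean_matrix: GenotypeMatrix
    observed_matrix: GenotypeMatrix
    memberships: Dict[str, str]  # sample id -> clone/node id
    clone_edges: List[Tuple[str, str, float]]
    meta: Dict[str, object] = field(default_factory=dict)


def _spawn(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_tumor_evolution(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> List[EvolutionNode]:
    """Grow the evolutionary tree: founder (all-reference, advantage 1),
    then n_nodes-1 advantage-weighted birth events."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.m_sites
    nodes = [EvolutionNode(0, None, 1.0, np.zeros(m, dtype=np.int8))]
    for i in range(1, config.n_nodes):
        adv = np.array([nd.advantage for nd in nodes])
        parent = int(rng.choice(len(nodes), p=adv / adv.sum()))
        child_adv = max(
            nodes[parent].advantage + rng.uniform(-config.advantage_step, config.advantage_step),
            ADVANTAGE_FLOOR,
        )
        n_mut = min(int(rng.poisson(config.mean_mutations_per_edge)), m)
        loci = rng.choice(m, size=n_mut, replace=False) if n_mut else np.array([], dtype=int)
        seq = nodes[parent].sequence.copy()
        seq[loci] ^= 1
        nodes.append(EvolutionNode(i, parent, child_adv, seq, n_mut))
    return nodes


def sample_cells(
    nodes: Sequence[EvolutionNode],
    n_samples: int,
    rng_or_seed,
) -> List[int]:
    """Draw node ids with replacement, weighted by advantage."""
    if not nodes:
        raise ValueError("empty tree")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    adv = np.array([nd.advantage for nd in nodes])
    return [int(x) for x in rng.choice(len(nodes), size=n_samples, p=adv / adv.sum())]


def apply_sequencing_noise(
    matrix: GenotypeMatrix,
    fp: float,
    fn: float,
    missing: float,
    rng_or_seed,
) -> GenotypeMatrix:
    """Independent per-entry noise on a binary-coded matrix: reference
    flips to variant with prob fp, variant to reference with prob fn, then
    the entry is masked to missing with prob missing."""
    for r in (fp, fn, missing):
        if not 0.0 <= r <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    states = matrix.states
    if not np.all(np.isin(states, (REF_STATE, VAR_STATE))):
        raise ValueError("noise model expects a clean reference/variant matrix")
    u = rng.random(states.shape)
    out = states.copy()
    out[(states == REF_STATE) & (u < fp)] = VAR_STATE
    out[(states == VAR_STATE) & (u < fn)] = REF_STATE
    out[rng.random(states.shape) < missing] = MISSING
    return GenotypeMatrix(list(matrix.loci_ids), list(matrix.sample_ids), out)


def _binary_to_matrix(binary: np.ndarray, sample_ids: List[str]) -> GenotypeMatrix:
    """(m, n) 0/1 grid -> ten-state coded GenotypeMatrix."""
    states = np.where(binary == 0, REF_STATE, VAR_STATE).astype(np.int8)
    loci = [f"locus{t}" for t in range(binary.shape[0])]
    return GenotypeMatrix(loci, sample_ids, states)


def _finish_dataset(
    clone_edges, memberships, clean_binary, sample_ids, config_like, rng_noise, meta
) -> SimulatedDataset:
    clones = set(memberships.values())
    for a, b, _ in clone_edges:
        clones.update((a, b))
    truth = clone_tree_to_sample_tree(clone_edges, memberships, clone_ids=sorted(clones))
    clean = _binary_to_matrix(clean_binary, sample_ids)
    observed = apply_sequencing_noise(
        clean,
        config_like["fp"],
        config_like["fn"],
        config_like["missing"],
        rng_noise,
    )
    return SimulatedDataset(truth, clean, observed, memberships, list(clone_edges), meta)


def simulate_tumor(config: SimulationConfig) -> SimulatedDataset:
    """Three phases: evolution, advantage-weighted cell sampling, noise."""
    rng_evo, rng_sample, rng_noise = _spawn(config.seed, 3)
    nodes = simulate_tumor_evolution(config, rng_evo)
    picks = sample_cells(nodes, config.n_samples, rng_sample)
    sample_ids = [f"cell{i}" for i in range(config.n_samples)]
    memberships = {sid: f"n{p}" for sid, p in zip(sample_ids, picks)}
    clone_edges = [
        (f"n{nd.parent}", f"n{nd.id}", float(nd.n_new_mutations))
        for nd in nodes
        if nd.parent is not None
    ]
    clean_binary = np.column_stack([nodes[p].sequence for p in picks])
    meta = {"mode": "tumor", "config": config.__dict__ | {}, "node_advantages": [nd.advantage for nd in nodes]}
    return _finish_dataset(
        clone_edges,
        memberships,
        clean_binary,
        sample_ids,
        {"fp": config.fp_rate, "fn": config.fn_rate, "missing": config.missing_rate},
        rng_noise,
        meta,
    )


def _uniform_labeled_tree(n: int, rng: np.random.Generator) -> List[Tuple[int, int]]:
    """Uniform random labeled tree on n nodes via a Pruefer sequence."""
    if n == 1:
        return []
    if n == 2:
        return [(0, 1)]
    prufer = [int(x) for x in rng.integers(0, n, size=n - 2)]
    degree = [1] * n
    for x in prufer:
        degree[x] += 1
    edges = []
    import heapq

    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for x in prufer:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u, v = sorted(leaves)
    edges.append((u, v))
    return edges


def simulate_clonal(
    n_clones: int,
    n_samples: int,
    m_sites: int,
    fp_rate: float = 0.015,
    fn_rate: float = 0.10,
    missing_rate: float = 0.07,
    mean_mutations: Optional[float] = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Clone-tree simulation under the infinite-sites assumption.

    A uniform random labeled tree over ``n_clones`` clones is rooted at
    clone 0 (the unmutated founder).  With ``mean_mutations=None`` every
    locus is assigned to one uniformly chosen clone edge, so each site
    mutates exactly once; with a Poisson per-edge mean, each edge draws its
    mutation count and loci come from the shrinking pool of never-mutated
    sites (an error is raised if the draws demand more loci than
    ``m_sites`` provides).  Cells are assigned to clones uniformly.
    """
    if n_clones < 1:
        raise ValueError("need at least one clone")
    if n_samples < 1 or m_sites < 1:
        raise ValueError("need at least one sample and one site")
    rng_tree, rng_mut, rng_sample, rng_noise = _spawn(seed, 4)
    edges = _uniform_labeled_tree(n_clones, rng_tree)
    # orient away from clone 0
    children: Dict[int, List[int]] = {i: [] for i in range(n_clones)}
    adj: Dict[int, List[int]] = {i: [] for i in range(n_clones)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    parent = {0: None}
    order = [0]
    stack = [0]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in parent:
                parent[y] = x
                children[x].append(y)
                order.append(y)
                stack.append(y)
    # mutation assignment, infinite sites
    edge_sites: Dict[int, np.ndarray] = {}  # child clone -> loci mutated on its edge
    if n_clones > 1:
        if mean_mutations is None:
            owner = rng_mut.integers(0, n_clones - 1, size=m_sites)
            non_root = [c for c in order if c != 0]
            for i, c in enumerate(non_root):
                edge_sites[c] = np.nonzero(owner == i)[0]
        else:
            counts = rng_mut.poisson(mean_mutations, size=n_clones - 1)
            if counts.sum() > m_sites:
                raise ValueError(
                    f"infinite-sites demand of {int(counts.sum())} mutations exceeds "
                    f"{m_sites} sites; increase m_sites"
                )
            pool = rng_mut.permutation(m_sites)
            pos = 0
            for i, c in enumerate([c for c in order if c != 0]):
                edge_sites[c] = np.sort(pool[pos : pos + counts[i]])
                pos += counts[i]
    sequences = {0: np.zeros(m_sites, dtype=np.int8)}
    for c in order:
        if c == 0:
            continue
        seq = sequences[parent[c]].copy()
        seq[edge_sites[c]] ^= 1
        sequences[c] = seq
    clone_edges = [
        (f"c{parent[c]}", f"c{c}", float(len(edge_sites[c]))) for c in order if c != 0
    ]
    picks = [int(x) for x in rng_sample.integers(0, n_clones, size=n_samples)]
    sample_ids = [f"cell{i}" for i in range(n_samples)]
    memberships = {sid: f"c{p}" for sid, p in zip(sample_ids, picks)}
    clean_binary = np.column_stack([sequences[p] for p in picks])
    meta = {
        "mode": "clonal",
        "n_clones": n_clones,
        "n_samples": n_samples,
        "m_sites": m_sites,
        "fp_rate": fp_rate,
        "fn_rate": fn_rate,
        "missing_rate": missing_rate,
        "mean_mutations": mean_mutations,
        "seed": seed,
        "edge_sites": {f"c{c}": [int(x) for x in sites] for c, sites in edge_sites.items()},
    }
    return _finish_dataset(
        clone_edges,
        memberships,
        clean_binary,
        sample_ids,
        {"fp": fp_rate, "fn": fn_rate, "missing": missing_rate},
        rng_noise,
        meta,
    )
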