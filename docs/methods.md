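# Methods

## Model and objective

Cells are length-m genotype vectors over the 11-state alphabet Σ + μ:
the ten unordered diploid genotypes over {A, C, G, T} plus the missing
state μ (`X/X`).  Pairs are stored in alphabetical order, so `T/A` and
`A/T` are one state.  A lineage tree is an unrooted tree whose nodes carry
sequences: samples (observed, possibly with missing loci) and inferred
ancestors (always missing-free).  The objective is minimum total edge cost,
with edge cost the sum over loci of the per-locus cost c:

| pair | cost | rationale |
|---|---|---|
| c(x, x), x observed | `match_cost` (0) | no change |
| c(x, y), x ≠ y observed | `mismatch_cost` (1) | one substitution |
| c(μ, x) | `mismatch_cost`/2 + ε | midpoint of all imputations |
| c(μ, μ) | 0 | two unknowns carry no evidence of change |

ε (default 10⁻⁵) must be positive: with c(μ, x) = 0.5 exactly, a missing
sequence placed between two observed sequences at distance 1 would be
cost-neutral and tree selection would be driven by tie-breaking; the ε makes
imputable placements strictly non-free.  The midpoint value is the unique
scale (up to ε) at which the extended table still satisfies the triangle
inequality — the test suite checks all 11³ triples, and checks that the
tempting c(μ, x) = 0 assignment provably violates it.  A symmetric 11×11
cost-matrix override is accepted for non-uniform costs; asymmetric (Dollo)
costs are out of scope.

## Inference algorithm

1. **Spanning-tree initialization.**  Kruskal over all pairwise sequence
   costs, ties broken by (cost, min index, max index) so the tree is
   deterministic.
2. **Examination.**  For every sample subset K (sizes 3..k, ascending,
   lexicographic) and every unrooted leaf-labeled topology on K (all
   internal nodes degree 3; (2|K|−5)!! of them), a per-locus Sankoff DP
   computes the optimal internal sequences.  Internal states range over the
   ten observed states only — with a mismatch-constant cost the optimum is
   always attained at an observed state, so excluding μ loses nothing and
   guarantees missing-free ancestors.  DP ties resolve to the lowest state
   code at every backtrack.  The candidate's *bridges* — the maximum-cost
   set of |K|−1 current-tree edges whose removal leaves one terminal of K
   per component — are found greedily (repeatedly cut the costliest edge on
   a path between still-connected terminals; an exchange argument gives
   optimality, and the brute-force subset search in the tests agrees).  If
   gain = cost(bridges) − cost(candidate) exceeds the threshold (default 0,
   configurable), the candidate is pushed on a stack, the bridges are
   removed, and for each bridge a replacement edge joins the two terminals
   whose components it separated, at cost cost(bridge) − gain.  The full
   gain is charged to every bridge's replacement, following the scheme's
   plain description; pair subsets are skipped since a bare edge can never
   beat the path already connecting its endpoints.
3. **Evaluation.**  Candidates pop LIFO; one is accepted iff its terminals
   lie in pairwise-distinct components of a union-find over previously
   accepted candidates, which are then merged.  This keeps the accepted set
   loop-free.
4. **Application.**  Accepted components are instantiated (the DP is re-run
   with backtracking to materialize ancestral sequences — examination
   stores only costs, a pure optimization) and completed into a spanning
   tree by adding original sample-sample edges in increasing cost order.
5. **Post-processing.**  Missing sample loci are imputed from the most
   abundant state among tree neighbors (one synchronous pass over
   pre-imputation states; missing neighbor states are ignored; ties go to
   the lowest state code; in the degenerate case of no observed neighbor
   state the locus-wide majority is used).  Edge costs are recomputed on the
   imputed sequences — reported costs therefore reflect the final,
   missing-free tree.  Inferred nodes of degree ≤ 2 are then suppressed
   (degree-2 contraction sums the two edge costs, so sample-to-sample path
   lengths are unchanged).

For two-state missing-free inputs the scheme inherits the k-restricted
Steiner guarantees: cost ≤ 11/6 × optimum at k = 3 and ≤ 16/9 at k = 4.
The acceptance suite verifies this against an exact Dreyfus–Wagner oracle
on every set of 4–6 distinct length-4 binary sequences (14 196 instances)
plus 200 random length-6 instances; the worst observed ratio is ≈ 1.25,
far inside the bound.  `restricted_steiner_ratio(k)` exposes the
Borchers–Du bound (r·2ʳ + s)/((r+1)·2ʳ + s) for k = 2ʳ + s on how much the
k-restriction itself can cost.

The whole pipeline is deterministic: no randomness is used anywhere in
inference, and all ties have explicit rules.

## Tree-comparison measures

**Pairwise-distance error.**  For a tree T over samples, PD_T[i,j] is the
path length between samples i and j (edge costs, or hop counts with
`weight="unit"`); P̄D_T divides by the total over unordered pairs, making
the measure invariant to rescaling all branch lengths of either tree
(different methods use incomparable weight conventions).  D(T, T′) is the
L1 difference over unordered pairs, in [0, 2]; an all-zero-cost tree
normalizes to the zero matrix by convention.  Clone-based trees (ground
truths, clone-tree methods) are first expanded: each clone becomes an
inferred node with its member samples attached by zero-length edges, so
same-clone samples sit at distance 0.

**Split similarity.**  Every edge induces a bipartition {A, B} of the
samples; two splits score max(|A₁∩A₂|+|B₁∩B₂|, |A₁∩B₂|+|B₁∩A₂|).  A
maximum-weight one-to-one matching (Hungarian algorithm on the zero-padded
rectangular score matrix) between the two trees' split multisets is
normalized by the reference tree's self-score (n × its edge count).  The
score is 1 exactly on identical trees and provably ≤ 1 whenever the
reference has at most as many edges as the comparison tree; since the
reference may be the smaller tree, both normalizations are reported by the
CLI (`split_similarity_score(..., return_both=True)`).

## Synthetic data

**Tumor-growth simulator** (three phases: evolution, sampling, sequencing).
The founder is all-reference with fitness advantage 1.  Each of the
remaining `n_nodes − 1` birth events picks a parent with probability
proportional to advantage; the child's advantage is the parent's plus a
Uniform(−`advantage_step`, +`advantage_step`) perturbation floored at 10⁻³
(advantages must stay positive for the weighted draws), and the child gains
Poisson(`mean_mutations_per_edge`) binary flips at uniformly drawn loci —
flips, so back-mutations can occur.  Cells are drawn with replacement,
weighted by advantage.  Defaults (5 nodes, 50 cells, 200 sites, 20
mutations/edge) are the standard benchmark conditions; the founder
advantage, perturbation support, and floor are this package's choices where
the procedure's description leaves them open, and they are configurable.

**Clonal simulator.**  A uniform random labeled tree over `n_clones` clones
(via Prüfer sequences — the clone-tree distribution is otherwise
unspecified, and uniform is the least informative choice), rooted at the
unmutated founder clone 0.  Mutations obey infinite sites: by default every
locus is assigned to exactly one uniformly chosen edge (so the per-edge
mutation mean is `m_sites/(n_clones−1)` and is determined by the site
count); alternatively a Poisson per-edge mean draws loci from the shrinking
pool of never-mutated sites and raises an error if the draws demand more
loci than exist.  Cells are assigned to clones uniformly.  The recorded
ground truth is the clone tree (edge weights = mutation counts) expanded
with zero-length sample edges.

**Sequencing noise**, per entry and independent: reference→variant with the
false-positive rate, variant→reference with the false-negative rate
(allelic dropout), then masking to missing.  Defaults FP 1.5%, FN 10%,
missing 7% — rates observed in real single-cell variant-call panels.
Binary simulation output is coded 0 → `A/A`, 1 → `C/C`.

All generators draw from a single seed via deterministically spawned
per-phase substreams; identical seed and configuration give byte-identical
datasets.

What the simulators deliberately do not model: copy-number events and
deletions (the cost model is symmetric; irreversible events would need
asymmetric costs), doublets, read-count-level error processes, and
site-specific error rates.  Passing tests on these data therefore
demonstrate correctness of the algorithmic machinery and recovery under
idealized point-mutation noise, not performance on data dominated by
structural variation.

## Benchmark scales and known limitations

The clonal benchmark (10 datasets per setting, 50 cells, k = 3) runs in
about half a minute per setting on one core; the exhaustive
approximation-ratio suite takes about a minute.  These sizes were chosen so
the whole verification suite completes quickly while still covering every
instance class exhaustively where exhaustiveness is the point.

On the two benchmark settings (5 clones/20 sites and 10 clones/50 sites)
the pipeline attains mean tree distances of roughly 0.20–0.25 — its
reconstructions sit much closer to the ground truth than the reference
means of 0.84 and 0.68 reported for the same settings with the original
clonal-simulation tool.  The acceptance test for that reproduction asserts
the reference band and is expected to fail: the reference simulator's exact
output distribution is not recoverable from its one-paragraph description
(under our generator, the entire published range for all eight compared
methods lies at or above what a uniformly random tree scores), so the
benchmark numbers here are reported as computed rather than matched.  The
qualitative properties that do not depend on the generator's fine structure
— the recovery trend with rising mutation rate, metric bounds and
identities, approximation guarantees — all hold and are tested.

Run time grows roughly with n^k (subset enumeration dominates); k = 3 with
hundreds of cells is comfortable, k = 4 is practical for n up to ~50.
Candidate evaluation order, and hence the output tree, follows the fixed
subset/topology ordering, so results are reproducible across platforms.
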