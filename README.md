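# scelestial

Single-cell lineage tree inference by a k-restricted Steiner-tree
approximation, with principled missing-value handling, tumor/clonal
simulators, and tree-comparison metrics.

## The problem

Single-cell DNA sequencing gives a cell-by-cell view of somatic evolution —
of a tumor, or of healthy tissue development — but the data are noisy:
allelic dropout (false negatives around 10%), amplification errors (false
positives around 1.5%), and many missing calls.  Given an m-loci × n-cells
matrix *D* of diploid genotype calls (ten unordered states over {A,C,G,T},
plus a missing token `X/X`), the task is to reconstruct the lineage tree
relating the sampled cells, including the genotypes of their unobserved
ancestors.

## The method

Under a maximum-parsimony reading, lineage reconstruction is a Steiner tree
problem: find the minimum-cost tree containing all observed sequences,
where extra (ancestral) sequences may be added as branching points.  Edge
costs are summed per-locus costs

&nbsp;&nbsp;&nbsp;&nbsp;c(x, x) = 0, c(x, y) = 1 for x ≠ y,
c(μ, x) = 0.5 + ε, c(μ, μ) = 0,

with μ the missing state and ε = 10⁻⁵ a small tie-break.  Placing the
missing state exactly halfway between all observed states is what keeps
the cost function triangle-inequality-respecting (setting c(μ, x) = 0
would let any mismatch route through μ for free).

The exact Steiner problem is NP-hard; the solver here is the classic
exchange-based approximation: maintain a minimum spanning tree *M* over the
samples, and for every subset *K* of at most *k* samples and every unrooted
topology on *K*, compute the best ancestral sequences by a per-locus
small-parsimony dynamic program.  If the candidate component's cost beats
the cost of the spanning-tree *bridges* it can replace, the exchange is
recorded and *M* is updated with discounted replacement edges; a stack-based
screening pass then merges a loop-free subset of the recorded components
into the final tree.  For two-state, missing-free data this is an
11/6-approximation at k = 3 and 16/9 at k = 4.  Missing sample loci are
finally imputed from the most abundant state among tree neighbors, and
redundant inferred nodes (degree ≤ 2) are suppressed.

The package also implements the two evaluation measures used for
single-cell trees — the normalized pairwise-path-distance error
D(T, T′) = Σ_{i<j} |P̄D_T[i,j] − P̄D_T′[i,j]| ∈ [0, 2] and a
maximum-weight-matching split similarity ∈ [0, 1] — plus two synthetic-data
generators (a tumor-growth simulator with selection, and an infinite-sites
clonal simulator).

## Worked example

Four cells with three loci each, written as base strings (`X` = missing):

```python
from scelestial import run_scelestial, sequences_from_strings, to_newick

cells = sequences_from_strings(["CAC", "GAG", "GCC", "XAC"], ["a", "b", "c", "d"])
tree = run_scelestial(cells, k=3)
print(to_newick(tree))
```

Running `python examples/01_infer_small_tree.py` prints:

```
spanning-tree cost before improvement: 3.50003
final tree cost after imputation:      3.00000
  edge     a - d     cost 0
  edge     b - node0 cost 1
  edge     c - node0 cost 1
  edge     d - node0 cost 1
inferred ancestor node0: GAC
cell d imputed to: CAC   (missing locus copied from its neighbor)
newick: (b:1,c:1,(a:0)d:1)node0;
```

The initial spanning tree hangs every cell off the missing-bearing cell `d`
(cost 3.5 + 3ε); examining the triple {a, b, c} finds the ancestral genotype
`GAC`, whose star costs 3 — the exchange is applied, `d`'s missing locus is
imputed from its neighbor, and `d` ends up co-located with `a` (edge cost 0).

More narrative scripts live in `examples/` (simulate-and-score, tumor
growth, the approximation guarantee, rooting and imputation).

## Command line

```sh
scelestial infer    --input matrix.tsv --dialect tenstate -k 3 --out tree.nwk
scelestial simulate --mode clonal --nodes 5 --samples 50 --sites 20 --seed 1 --out-prefix sim
scelestial compare  --truth sim.truth.nwk --inferred tree.nwk
scelestial impute   --input matrix.tsv --out imputed.tsv
scelestial bench    --replicates 10 --seed 1
```

Genotype tables are TSV with loci as rows and samples as columns; the
`binary` dialect reads 0/1/NA matrices (0 → `A/A`, 1 → `C/C`).

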