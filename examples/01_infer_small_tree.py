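"""Infer a lineage tree for four cells, one of which has a missing locus.

The cells carry three homozygous genotypes each (written as base strings;
X marks a missing call).  The method starts from the minimum spanning tree
under the per-locus cost (mismatch 1, missing-observed 0.5 + 1e-5), grafts
the best three-leaf component found by the small-parsimony DP, and finally
imputes the missing locus from the tree neighborhood.
"""

from scelestial import (
    CostModel,
    build_mst,
    run_scelestial,
    sequences_from_strings,
    to_newick,
)
from scelestial.genotype import state_to_token

cells = sequences_from_strings(["CAC", "GAG", "GCC", "XAC"], ["a", "b", "c", "d"])
model = CostModel()

mst = build_mst(cells, model)
print(f"spanning-tree cost before improvement: {mst.total_cost():.5f}")

tree = run_scelestial(cells, k=3, model=model)
print(f"final tree cost after imputation:      {tree.total_cost():.5f}")
for u, v, c in tree.edges:
    print(f"  edge {u:>5} - {v:<5} cost {c:g}")
for node in tree.inferred_ids:
    seq = "".join(state_to_token(int(s))[0] for s in tree.sequence(node).states)
    print(f"inferred ancestor {node}: {seq}")
imputed = "".join(state_to_token(int(s))[0] for s in tree.sequence("d").states)
print(f"cell d imputed to: {imputed}   (missing locus copied from its neighbor)")
print("newick:", to_newick(tree))
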